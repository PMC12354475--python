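# Methods

## Network model

The AV node is modeled as two antegrade chains of excitable nodes — ten
fast-pathway (FP) and ten slow-pathway (SP) nodes — converging on a single
coupling node that represents the His/Purkinje junction and emits
ventricular activations 60 ms after transmitting. Atrial impulses enter
both chains simultaneously. Each node blocks impulses arriving inside its
refractory window and otherwise transmits with a conduction delay; both
quantities recover exponentially with the preceding diastolic interval
(time constants τ_R, τ_D; amplitudes ΔR, ΔD; floors R_min, D_min), six
parameters per pathway, twelve in total (θ). Blocked impulses do not reset
refractoriness; the boundary case t̃ = 0 conducts. The first impulse at a
node sees a repolarization time of zero, so its diastolic interval equals
its arrival time.

Propagation is event-driven: a priority queue ordered by (arrival time,
node index, insertion order) — the deterministic tie rule makes
simulations bit-reproducible. The adjacency is antegrade-only (entry →
… → exit → coupling per pathway); it is held in one place in the
simulator so alternative topologies (e.g. retrograde links) could be
configured without touching the event loop. Concealed conduction arises
naturally: impulses that enter but die inside a pathway still reset the
refractory clocks they touched.

Two implementations share this contract: a readable pure-Python reference
class (used by the benchmark generator and for single simulations) and a
numba batch engine that advances tens of thousands of particle states per
observed beat. Their exact agreement, and the agreement of both with an
independent fixed-step (0.01 ms) brute-force simulator, is enforced by
tests on randomized toy networks.

Per inter-beat interval the conduction properties φ = [R_FP, R_SP, D_FP,
D_SP] are the pathway-wise medians of the realized per-node R and D, the
delay multiplied by the number of nodes per pathway. A pathway silent in
an interval carries its previous value forward; with no previous value
the recovery curves are evaluated at the elapsed diastolic interval of
the pathway's entry node. This keeps φ defined at every beat.

The coupling node's refractory period is a per-dataset constant; the
estimation pipeline derives it from the data as the shortest observed RR
interval minus 50 ms (`coupling_from_rr`), the benchmark generator uses a
fixed 250 ms.

## Particle filters

Both filters track θ per beat with N particles; each particle stores θ,
its private model state saved at its previous simulated beat (invasive
mode) or previous trigger impulse (non-invasive mode), and is weighted by
a Gaussian observation kernel on the simulated-vs-observed beat mismatch,
σ_w = 30 ms (R-peak detection uncertainty; kept for synthetic data as a
study condition). Resampling is systematic (multinomial available for
oracle tests); weights are accumulated in log space. Parameters evolve by
a truncated Gaussian random walk (rejection against the prior box and the
pathway-ordering constraint).

The pathway-ordering constraint — the SP never has a longer refractory
period than the FP, nor a shorter conduction delay — is enforced at both
recovery limits (t̃ → 0 and t̃ → ∞), which by monotonicity guarantees it
at every diastolic interval.

The non-invasive filter evaluates atrial-timing uncertainty by copying
each resampled particle `n_ecg_copies` times and giving every copy a
fresh candidate AA series: a Gaussian random walk of activation times
whose mean is drawn from the per-interval f-wave features (exactly the
measured mean inverse f-wave frequency when the signal quality index is
at least 0.3) and whose standard deviation is four times the measured
σ_f. Each copy re-simulates from the state saved at the trigger impulse
of its previous beat, using the previous parameters before that beat and
the new parameters after. The replay may legitimately reproduce *earlier*
beats first (in-flight impulses; double ventricular responses where both
pathway arrivals transmit); the implementation therefore replays beats
until one exceeds the stored previous beat, requires some replayed beat
to match it within 1e-6 ms, and takes the first beat beyond it as the new
simulated beat. Copies failing the match are excluded (zero weight), as
are copies producing no beat before the horizon (previous beat + 5 s by
default).

If every weight in a step vanishes, the filter keeps the pre-weighting
ensemble with uniform weights and (in the non-invasive filter) rolls each
particle back to its previous beat/trigger so the next step retries with
fresh atrial realizations; the event is logged and flagged in the result.

### Defaults and their rationale

| quantity | default | why |
| --- | --- | --- |
| prior box (per node, ms) | R_min ∈ [250, 600], ΔR ∈ [0, 600], τ_R ∈ [50, 300]; D_min, ΔD ∈ [0, 60], τ_D ∈ [50, 300]; same for both pathways before the ordering constraint | spans the whole-pathway property magnitudes reported in patients (FP refractory periods up to ~1.2 s, whole-pathway delays up to ~1.2 s) |
| σ_w | 30 ms | R-peak timing uncertainty |
| propagation std (diag Σ) | 8% of each prior range per beat | calibrated on synthetic validation records (separate seed from all test records) so smoothed 95% credibility regions cover the truth at or slightly above the nominal rate; smaller kernels (1–2%) collapse the ensemble (effective sample size → 1 at isolated surprising beats) and destroy coverage |
| N, N_ECG, M | 1,000,000 / 25 / 20,000 | full-scale study conditions; overridden for desk-scale runs |
| AA increment floor | 30 ms | below physiological AF cycle lengths; sub-floor draws are resampled, not clipped |

The prior box and Σ are configuration: both belong to material not fully
specified by the main description of the method, and are documented here
as this package's own choices.

## Smoother

Forward-filtering backward-sampling: the final index of a trajectory is
drawn from the final filter weights; going backwards, each step's weights
are tilted by the Gaussian transition density toward the selected
next-step particle (same Σ as the filter) and renormalized. Zero-variance
parameters contribute a point mass (exact match or −∞). The backward
sweep is vectorized: transition log-densities are computed once per
unique selected next index via a matrix product over σ-scaled
coordinates, and per-trajectory categorical sampling shares one
cumulative distribution per unique index — exactly equivalent to naive
per-trajectory recomputation, which the enumeration tests verify on toy
instances.

## Synthetic benchmark

Each record holds a per-beat ground-truth parameter trend θ*(k) (bounded
Gaussian walk, default 1% of each prior range per beat, reflected at the
box and re-checked against the ordering constraint; constant and
step-change variants available), an AA series (Gaussian random walk,
mean 160 ms, std 20 ms — representative AF cycle lengths), the RR series
obtained by simulating the model on (θ*, AA), the per-beat φ*(k) from the
same run, and per-RR f-wave features derived from the AA series itself
(μ_f = mean inter-activation interval in the RR interval, σ_f = its
standard deviation, SQI fixed at 0.5). Records are internally consistent
by construction — re-simulating (θ*, AA) reproduces rr and φ*
bit-identically — and bit-reproducible from their seed.

What the benchmark does **not** emulate: QRST residuals and f-wave
tracking error (features come from the true AA series, so the feature →
AA-statistics link is cleaner than in real ECG), atrial spatial
organization (increments are i.i.d., real AF cycle series are
autocorrelated), R-peak jitter (observed beats are exact), and
patient-realistic parameter trajectories (θ* is drawn uniformly from the
prior, so some records sit in extreme corners of the parameter space that
fitted patient parameters would rarely occupy). Passing recovery tests on
this benchmark therefore demonstrates correctness and calibration of the
estimation machinery under matched model assumptions, not clinical
accuracy.

## Evaluation metrics

Posterior mode per beat: 5 ms histogram bins anchored at 0, ties to the
lowest bin. Beat-averaged absolute error l1̄; 1-min-average error lmin1̄
over non-overlapping windows anchored at the record start (a trailing
partial window of at least 30 s counts); normalized errors divide by the
per-property ground-truth range over the benchmark, recomputed per
benchmark. CR95 is the percentage of beats whose truth lies inside the
2.5–97.5 percentile band (linear interpolation). Bland–Altman agreement
and tilt-phase summaries (phase means, paired one-sided Wilcoxon
signed-rank tests with Shapiro–Wilk normality checks alongside) cover the
between-mode and autonomic-challenge analyses.

## Problem sizes used in the shipped experiments

The recovery experiments run five 60 s constant-truth records with
20,000 particles and 2,000 smoothing trajectories (invasive mode) and
2,000 × 5 copies (non-invasive mode); the reproduction script uses three
60 s random-walk records at 10,000 / 2,000 × 5 particles and 1,000
trajectories. These sizes keep a complete run in the minutes range on a
single CPU while preserving the qualitative structure of the full-scale
results (slow-pathway refractory period best identified; non-invasive
estimation degrading the slow-pathway delay most).

## Known limitations

* At desk-scale particle counts, ground truths near the upper corner of
  the prior (slow-pathway refractory periods ≳ 700 ms, long RR intervals)
  are covered by few initial particles; the posterior stays honestly wide
  (coverage is maintained) but its histogram mode can wander by ~100 ms.
* The non-invasive filter's replay-consistency exclusion preferentially
  removes long-latency particles when the candidate AA series are
  diffuse; combined with the weak likelihood constraint on atrial timing
  this biases the slow-pathway delay low — an exaggerated, desk-scale
  form of the expected non-invasive D_SP degradation. The agreement
  fraction between replayed and stored beats is exposed in the filter
  diagnostics.
* Fast-pathway properties are estimated with large uncertainty whenever
  few beats conduct through the FP; their errors in the reproduction
  script's output should be read with the matching CR95 values.
* No ventricular escape rhythm, no multiple slow pathways, no
  action-potential-level dynamics; parallel execution is not implemented
  (runs are strictly sequential and deterministic given the seed).
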