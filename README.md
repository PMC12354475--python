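# avnodal

Beat-to-beat Bayesian estimation of atrioventricular (AV) node conduction
properties during atrial fibrillation (AF).

## The problem

During AF the atria bombard the AV node with rapid, irregular impulses; the
node's two conduction routes — the fast pathway (FP) and the slow pathway
(SP) — filter this input and thereby set the ventricular rhythm. Their
refractory periods and conduction delays, φ = [R_FP, R_SP, D_FP, D_SP],
are modulated beat to beat by the autonomic nervous system but cannot be
measured directly during AF. This package estimates them, per heartbeat,
from timing data alone:

* **invasive mode** ("EGM"): an observed RR series plus an observed atrial
  activation (AA) series;
* **non-invasive mode** ("ECG"): an RR series plus per-interval f-wave
  features (mean and standard deviation of the inverse fibrillatory
  frequency, and a signal quality index), from which candidate AA series
  are generated as Gaussian random walks.

## The model and the estimator

The AV node is a network of 21 nodes: ten per pathway plus a coupling node
(fixed delay 60 ms; refractory period set per dataset to the shortest
observed RR interval minus 50 ms). Per node, refractoriness and delay
recover exponentially with the preceding diastolic interval t̃:

    R(t̃) = R_min + ΔR · (1 − e^(−t̃/τ_R))
    D(t̃) = D_min + ΔD · e^(−t̃/τ_D)
    t̃    = t(n) − (t(n−1) + R(n−1))     (t̃ < 0 ⇒ impulse blocked)

giving 12 parameters θ (six per pathway). Impulses propagate through an
event queue (a modified shortest-arrival-first scheme); each simulated
inter-beat interval is summarized into φ by pathway-wise medians of the
realized R and per-node D (× 10 for the whole pathway).

θ is tracked per beat by a sequential Monte Carlo (particle) filter: each
particle carries a parameter vector and a saved model state, simulates the
next ventricular beat V̂ₖ, and is weighted by N(V̂ₖ − Vₖ | 0, σ_w²) with
σ_w = 30 ms. The non-invasive filter additionally generates a fresh AA
series per particle copy and re-simulates the previous interval for
bookkeeping consistency, excluding particles whose replayed beat diverges.
A forward-filtering backward-sampling (FFBS) smoother then draws M whole
trajectories of θ (and φ) from the smoothing distribution; reported
estimates are per-beat histogram modes (5 ms bins) with 95% credibility
regions from the 2.5/97.5 percentiles.

## Worked example

```python
import numpy as np
import avnodal as av
from avnodal.benchmark import BenchmarkSpec, generate_benchmark
from avnodal import evaluation as ev

rec = generate_benchmark(BenchmarkSpec(n_records=1, duration_s=60.0,
                                       trend_dynamics="constant", seed=3))[0]
cfg = av.FilterConfig(n_particles=20_000, seed=1)
res = av.run_egm_pf(rec.rr, rec.aa, cfg, coupling=rec.coupling)
post = av.run_ffbs(res, 2_000, np.random.default_rng(2))
mode = ev.mode_trend(post.phis)
rep = ev.l1_errors(mode, rec.phi_star, rec.rr)
print(np.round(rep.l1_mean, 1))                      # [96.6 16.  90.9 20.2]
print(np.round(ev.cr95_coverage(post.phis, rec.phi_star), 1))  # [100. 100. 100. 100.]
```

The first line is the beat-averaged absolute error (ms) of the posterior
mode against the ground truth for [R_FP, R_SP, D_FP, D_SP]: the slow
pathway's properties are recovered to ~16–20 ms on this record — they
dominate the observable RR timing — while the fast-pathway properties,
which influence fewer beats, carry several times that error. The second
line is the fraction of beats (in %) where the truth falls inside the 95%
credibility band: here the bands cover the truth everywhere
(conservative, consistent with coverage slightly above the nominal 95%).

The same workflows are scriptable from the shell:

```bash
avnodal simulate --records 1 --duration 60 -o bench
avnodal filter-egm --rr bench/record_000/rr.csv --aa bench/record_000/aa.csv \
        --particles 20000 --seed 1 -o filt
avnodal smooth --filter-dir filt -m 2000 -o post
avnodal evaluate --posterior post --truth bench/record_000 -o report
```

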