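"""Synthetic ground-truth benchmark for the estimation pipeline.

Generates records that mirror the simulated-data evaluation setup: a
per-beat parameter trend theta*(k) inside the prior box, an atrial
activation series, per-RR f-wave features, the RR series obtained by
running the network model on (theta*, AA), and the per-beat ground-truth
conduction properties phi*(k) from the same run.  Every record is
internally consistent: re-simulating (theta*, AA) reproduces rr and phi*
bit-identically.

Default conditions: 50 records of 60 s; atrial input a Gaussian random
walk with mean interval 160 ms and increment std 20 ms (representative AF
cycle lengths); theta* follows a bounded Gaussian random walk with
per-beat steps of 1% of each prior range (gentle physiological drift),
optionally with configurable step changes; SQI is a constant 0.5
(above the 0.3 sufficiency threshold) so the f-wave-driven generator mean
is noiseless unless a test injects feature noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atrial import AAGeneratorDraw, AASeries, FWaveFeatures, generate_aa_series
from .filters import PriorBounds, default_prior, ordering_ok, sample_prior, FilterConfig
from .model import (
    ConductionProperties,
    CouplingNodeConfig,
    ModelParameters,
    THETA_COLUMNS,
    simulate_rr_series,
)

__all__ = [
    "BenchmarkSpec",
    "GroundTruthTrend",
    "generate_parameter_trend",
    "generate_benchmark",
    "import_aa_from_wfdb",
]


@dataclass(frozen=True)
class BenchmarkSpec:
    """Construction parameters of a synthetic benchmark.

    ``trend_dynamics`` is ``"random_walk"`` (bounded Gaussian walk, std
    ``trend_std`` per beat, reflected at the prior box and re-checked
    against the pathway ordering) or ``"constant"``.  ``step_changes``
    optionally adds abrupt shifts: a list of (beat_index, 12-vector
    delta).
    """

    n_records: int = 50
    duration_s: float = 60.0
    aa_mean_ms: float = 160.0
    aa_std_ms: float = 20.0
    sqi: float = 0.5
    trend_dynamics: str = "random_walk"
    trend_std: np.ndarray | None = None  # default: 1% of prior range per beat
    step_changes: tuple = ()
    coupling_refractory_ms: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.duration_s <= 0:
            raise ValueError("need n_records >= 1 and duration > 0")
        if self.trend_dynamics not in ("random_walk", "constant"):
            raise ValueError(f"unknown trend dynamics {self.trend_dynamics!r}")


@dataclass
class GroundTruthTrend:
    """One benchmark record: trend, inputs, simulated output, ground truth."""

    theta_star: np.ndarray  # (K, 12)
    phi_star: np.ndarray  # (K, 4)
    aa: AASeries
    features: FWaveFeatures
    rr: np.ndarray  # (K,) beat times
    coupling: CouplingNodeConfig
    seed: int = 0

    @property
    def n_beats(self) -> int:
        return len(self.rr)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.theta_star, columns=THETA_COLUMNS).to_csv(d / "theta_star.csv", index=False)
        pd.DataFrame(self.phi_star, columns=["r_fp", "r_sp", "d_fp", "d_sp"]).to_csv(
            d / "phi_star.csv", index=False
        )
        pd.DataFrame({"aa_ms": self.aa.activation_times}).to_csv(
            d / "aa.csv", index=False, float_format="%.6f"
        )
        pd.DataFrame({"rr_ms": self.rr}).to_csv(d / "rr.csv", index=False, float_format="%.6f")
        self.features.to_frame().to_csv(d / "features.csv", index=False)
        manifest = {
            "seed": self.seed,
            "coupling": {"refractory": self.coupling.refractory, "delay": self.coupling.delay},
            "n_beats": int(self.n_beats),
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "GroundTruthTrend":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        return cls(
            theta_star=pd.read_csv(d / "theta_star.csv")[THETA_COLUMNS].to_numpy(float),
            phi_star=pd.read_csv(d / "phi_star.csv").to_numpy(float),
            aa=AASeries(pd.read_csv(d / "aa.csv")["aa_ms"].to_numpy(float)),
            features=FWaveFeatures.from_frame(pd.read_csv(d / "features.csv")),
            rr=pd.read_csv(d / "rr.csv")["rr_ms"].to_numpy(float),
            coupling=CouplingNodeConfig(**manifest["coupling"]),
            seed=manifest["seed"],
        )


def _trend_std(spec: BenchmarkSpec, prior: PriorBounds) -> np.ndarray:
    # study condition, deliberately decoupled from the filters' propagation
    # kernel: gentle physiological drift of ~1% of each prior range per beat
    if spec.trend_std is not None:
        return np.asarray(spec.trend_std, dtype=float)
    return 0.01 * prior.range


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect into [lo, hi] (single reflection suffices for small steps)."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return np.clip(x, lo, hi)


def generate_parameter_trend(
    spec: BenchmarkSpec,
    prior: PriorBounds,
    rng: np.random.Generator,
    n_beats: int,
    theta0: np.ndarray | None = None,
) -> np.ndarray:
    """Per-beat theta* sequence inside the prior box, ordering-consistent at
    every beat.

    Random-walk steps that land outside the box are reflected; steps that
    break the pathway ordering are redrawn (up to 100 times, then held).
    """
    if theta0 is None:
        cfg = FilterConfig(n_particles=1, prior=prior, seed=0)
        theta0 = sample_prior(cfg, rng, 1)[0]
    theta0 = np.asarray(theta0, dtype=float)
    if not ordering_ok(theta0[None, :])[0]:
        raise ValueError("theta0 violates the pathway-ordering constraint")
    out = np.empty((n_beats, 12))
    out[0] = theta0
    if spec.trend_dynamics == "constant":
        out[:] = theta0
    else:
        std = _trend_std(spec, prior)
        for k in range(1, n_beats):
            cur = out[k - 1]
            nxt = cur
            for _ in range(100):
                cand = _reflect(cur + rng.normal(0.0, std), prior.lower, prior.upper)
                if ordering_ok(cand[None, :])[0]:
                    nxt = cand
                    break
            out[k] = nxt
    for beat_idx, delta in spec.step_changes:
        if beat_idx < n_beats:
            shifted = _reflect(out[beat_idx:] + np.asarray(delta, float),
                               prior.lower, prior.upper)
            ok = ordering_ok(shifted)
            out[beat_idx:][ok] = shifted[ok]
    return out


def features_from_aa(
    aa: AASeries, rr: np.ndarray, sqi: float, fallback_std: float
) -> FWaveFeatures:
    """Derive per-RR f-wave features from the atrial series itself.

    mu_f is the mean inter-activation interval among activations falling
    in the RR interval, sigma_f their standard deviation; intervals with
    fewer than two activations fall back to the record-level statistics.
    The SQI is synthesized as a constant.
    """
    times = aa.activation_times
    inc = np.diff(times)
    mid = times[1:]  # an increment "belongs" to its ending activation
    rec_mu = float(inc.mean())
    edges = np.concatenate([[0.0], rr])
    mu_f = np.empty(len(rr))
    sg_f = np.empty(len(rr))
    for k in range(len(rr)):
        sel = inc[(mid > edges[k]) & (mid <= edges[k + 1])]
        mu_f[k] = sel.mean() if sel.size >= 1 else rec_mu
        sg_f[k] = sel.std(ddof=0) if sel.size >= 2 else fallback_std
    return FWaveFeatures(mu_f=mu_f, sigma_f=sg_f, sqi=np.full(len(rr), sqi))


def generate_benchmark(
    spec: BenchmarkSpec,
    prior: PriorBounds | None = None,
    n_per_path: int = 10,
) -> list[GroundTruthTrend]:
    """Generate ``spec.n_records`` independent ground-truth records."""
    prior = default_prior() if prior is None else prior
    master = np.random.SeedSequence(spec.seed)
    records = []
    for rec_seed in master.spawn(spec.n_records):
        rng = np.random.default_rng(rec_seed)
        horizon = spec.duration_s * 1000.0
        aa = generate_aa_series(
            AAGeneratorDraw(mu_alpha=spec.aa_mean_ms, sigma_alpha=spec.aa_std_ms),
            start_time=0.0,
            horizon=horizon,
            rng=rng,
        )
        coupling = CouplingNodeConfig(refractory=spec.coupling_refractory_ms)
        # generous upper bound on beat count: one beat per coupling refractory
        max_beats = int(horizon / max(spec.coupling_refractory_ms, 100.0)) + 8
        trend = generate_parameter_trend(spec, prior, rng, max_beats)
        theta_objs = [ModelParameters.from_vector(v) for v in trend]
        rr, phis = simulate_rr_series(theta_objs, aa.activation_times, coupling,
                                      n_per_path=n_per_path)
        if rr.size == 0:
            warnings.warn("benchmark record produced no ventricular beats; skipped")
            continue
        k = rr.size
        rec = GroundTruthTrend(
            theta_star=trend[:k],
            phi_star=np.stack([p.to_vector() for p in phis]),
            aa=aa,
            features=features_from_aa(aa, rr, spec.sqi, spec.aa_std_ms / 4.0),
            rr=rr,
            coupling=coupling,
            seed=int(rec_seed.entropy) if isinstance(rec_seed.entropy, int) else 0,
        )
        records.append(rec)
    return records


def import_aa_from_wfdb(record_path, annotator: str = "atr") -> AASeries:
    """Read atrial activation times from a WFDB annotation file (optional helper).

    Requires the ``wfdb`` package; annotation sample indices are converted
    to ms using the record's sampling frequency.  No detection algorithm
    is applied -- annotations are passed through and validated.
    """
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - wfdb is an optional extra
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package"
        ) from exc
    ann = wfdb.rdann(str(record_path), annotator)
    times_ms = np.asarray(ann.sample, dtype=float) / float(ann.fs) * 1000.0
    return AASeries(activation_times=times_ms)
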