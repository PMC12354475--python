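"""Atrial activation series: observed (EGM) and f-wave-driven generation (ECG).

During AF the atrial input to the AV node is a rapid, irregular impulse
train.  With an intracardiac electrogram the activation times are observed
directly; from the surface ECG only f-wave statistics are available, so
candidate AA series are generated as Gaussian random walks of the
activation *times*: inter-activation intervals are i.i.d.
``Normal(mu_alpha, sigma_alpha^2)``, truncated below at a positive floor.

Per RR interval the f-wave analysis supplies the mean ``mu_f`` and
standard deviation ``sigma_f`` of the inverse f-wave frequency (the atrial
cycle length) and a signal quality index (SQI).  The generator mean is
drawn as ``mu_alpha ~ Normal(mu_f, max(0, 0.3 - SQI)^4)`` -- computed in
seconds, where the expression is dimensionally consistent, then converted
to ms -- so that an SQI of at least 0.3 pins ``mu_alpha`` to ``mu_f``
exactly; ``sigma_alpha`` is set to ``4 * sigma_f`` (empirical factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AASeries",
    "FWaveFeatures",
    "AAGeneratorDraw",
    "draw_interval_mean",
    "interval_stddev",
    "generate_aa_series",
    "MIN_INCREMENT_MS",
    "SQI_THRESHOLD",
]

#: Floor for generated inter-activation intervals (ms); below physiological
#: AF cycle lengths.  Sub-floor draws are resampled, not clipped.
MIN_INCREMENT_MS = 30.0

#: SQI at or above this value is deemed sufficient: the generator mean is
#: then taken to be the measured mean inverse f-wave frequency exactly.
SQI_THRESHOLD = 0.3


@dataclass(frozen=True)
class AASeries:
    """Strictly increasing atrial activation timestamps (ms)."""

    activation_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.activation_times, dtype=float)
        if times.size == 0:
            raise ValueError("AA series must be nonempty")
        if np.any(~np.isfinite(times)):
            raise ValueError("AA series contains non-finite timestamps")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("AA series must be strictly increasing")
        object.__setattr__(self, "activation_times", times)

    def __len__(self) -> int:
        return len(self.activation_times)


@dataclass(frozen=True)
class FWaveFeatures:
    """Per-RR-interval f-wave features: mu_f (ms), sigma_f (ms), SQI in [0, 1]."""

    mu_f: np.ndarray
    sigma_f: np.ndarray
    sqi: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu_f, dtype=float))
        sg = np.atleast_1d(np.asarray(self.sigma_f, dtype=float))
        sq = np.atleast_1d(np.asarray(self.sqi, dtype=float))
        if not (mu.shape == sg.shape == sq.shape):
            raise ValueError("feature arrays must have matching shapes")
        if np.any(mu <= 0):
            raise ValueError("mu_f must be > 0")
        if np.any(sg < 0):
            raise ValueError("sigma_f must be >= 0")
        object.__setattr__(self, "mu_f", mu)
        object.__setattr__(self, "sigma_f", sg)
        object.__setattr__(self, "sqi", sq)

    def __len__(self) -> int:
        return len(self.mu_f)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rr_index": np.arange(len(self.mu_f)),
                "mu_f_ms": self.mu_f,
                "sigma_f_ms": self.sigma_f,
                "sqi": self.sqi,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FWaveFeatures":
        return cls(
            mu_f=df["mu_f_ms"].to_numpy(float),
            sigma_f=df["sigma_f_ms"].to_numpy(float),
            sqi=df["sqi"].to_numpy(float),
        )


@dataclass(frozen=True)
class AAGeneratorDraw:
    """One realized random-walk parameterization: mu_alpha > 0, sigma_alpha >= 0 (ms)."""

    mu_alpha: float
    sigma_alpha: float

    def __post_init__(self) -> None:
        if not self.mu_alpha > 0:
            raise ValueError("mu_alpha must be > 0")
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be >= 0")


def draw_interval_mean(
    mu_f_ms: float | np.ndarray,
    sqi: float | np.ndarray,
    rng: np.random.Generator,
    floor_ms: float = MIN_INCREMENT_MS,
) -> np.ndarray:
    """Sample the walk mean ``mu_alpha`` (ms) given f-wave features.

    ``mu_alpha ~ Normal(mu_f, max(0, 0.3 - SQI)^4)`` with the variance in
    seconds squared; with SQI >= 0.3 the draw is exact.  Results are
    floored at ``floor_ms`` to stay physiological.
    """
    mu_s = np.atleast_1d(np.asarray(mu_f_ms, dtype=float)) / 1000.0
    sqi = np.atleast_1d(np.asarray(sqi, dtype=float))
    var_s2 = np.maximum(0.0, SQI_THRESHOLD - sqi) ** 4
    draw_s = rng.normal(mu_s, np.sqrt(var_s2))
    return np.maximum(draw_s * 1000.0, floor_ms)


def interval_stddev(sigma_f_ms: float | np.ndarray) -> np.ndarray:
    """Walk standard deviation ``sigma_alpha = 4 * sigma_f`` (ms)."""
    return 4.0 * np.atleast_1d(np.asarray(sigma_f_ms, dtype=float))


def sample_increments(
    mu_alpha: float,
    sigma_alpha: float,
    size: int,
    rng: np.random.Generator,
    floor_ms: float = MIN_INCREMENT_MS,
    max_resample: int = 100,
) -> np.ndarray:
    """i.i.d. Normal(mu_alpha, sigma_alpha^2) increments with sub-floor draws resampled."""
    inc = rng.normal(mu_alpha, sigma_alpha, size)
    for _ in range(max_resample):
        bad = inc < floor_ms
        if not bad.any():
            break
        inc[bad] = rng.normal(mu_alpha, sigma_alpha, int(bad.sum()))
    np.maximum(inc, floor_ms, out=inc)  # pathological (mu far below floor) safety
    return inc


def generate_aa_series(
    draw: AAGeneratorDraw,
    start_time: float,
    horizon: float,
    rng: np.random.Generator,
    floor_ms: float = MIN_INCREMENT_MS,
) -> AASeries:
    """Generate a random-walk AA series anchored at ``start_time``.

    The first impulse sits at ``start_time`` itself; subsequent activation
    times add i.i.d. truncated-normal increments until ``horizon`` is
    passed.
    """
    if not horizon > start_time:
        raise ValueError("horizon must exceed start_time")
    times = [float(start_time)]
    t = float(start_time)
    # draw in blocks to limit generator round-trips
    est = max(8, int((horizon - start_time) / max(draw.mu_alpha, floor_ms)) + 4)
    done = False
    while not done:
        for inc in sample_increments(draw.mu_alpha, draw.sigma_alpha, est, rng, floor_ms):
            if t + inc > horizon:
                done = True
                break
            t += inc
            times.append(t)
    return AASeries(activation_times=np.array(times, dtype=float))
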