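"""Evaluation metrics for smoothed posterior trends.

Covers every reported summary: per-beat posterior mode trends (5 ms
histogram bins), beat-wise l1 errors against ground truth with and
without range normalization, 1-min-average errors, 95% credibility-region
coverage, Bland-Altman concordance between two mode trends, and
tilt-phase averages with paired one-sided Wilcoxon tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PROPERTY_NAMES",
    "mode_trend",
    "l1_errors",
    "cr95_coverage",
    "bland_altman",
    "tilt_analysis",
    "EvaluationReport",
    "TiltSummary",
]

PROPERTY_NAMES = ["r_fp", "r_sp", "d_fp", "d_sp"]


@dataclass
class EvaluationReport:
    """Per-property error summary of one record (all times ms, percentages in [0, 100])."""

    l1_mean: np.ndarray  # (P,)
    l1_min: np.ndarray  # (P,) 1-min-average error
    l1_norm: np.ndarray  # (P,) %
    l1_min_norm: np.ndarray  # (P,) %
    cr95: np.ndarray | None  # (P,) %
    normalization_range: np.ndarray  # (P,)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "property": PROPERTY_NAMES[: len(self.l1_mean)],
            "l1_mean_ms": self.l1_mean,
            "l1_min_ms": self.l1_min,
            "l1_norm_pct": self.l1_norm,
            "l1_min_norm_pct": self.l1_min_norm,
            "range_ms": self.normalization_range,
        }
        if self.cr95 is not None:
            data["cr95_pct"] = self.cr95
        return pd.DataFrame(data)


def mode_trend(samples: np.ndarray, bin_width: float = 5.0) -> np.ndarray:
    """Per-beat histogram mode of posterior samples.

    ``samples`` has shape (M, K) or (M, K, P); per beat (and property) the
    M values are sorted into bins ``[i*w, (i+1)*w)`` anchored at 0 and the
    center of the maximal-count bin is returned (ties go to the lowest
    bin).  Order of the samples is irrelevant.
    """
    arr = np.asarray(samples, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    m, k, p = arr.shape
    idx = np.floor(arr / bin_width).astype(np.int64)
    offset = idx.min()
    idx -= offset
    n_bins = int(idx.max()) + 1
    out = np.empty((k, p))
    for j in range(p):
        for beat in range(k):
            counts = np.bincount(idx[:, beat, j], minlength=n_bins)
            out[beat, j] = (counts.argmax() + offset + 0.5) * bin_width
    return out[:, 0] if squeeze else out


def l1_errors(
    mode: np.ndarray,
    truth: np.ndarray,
    rr: np.ndarray,
    normalization_range: np.ndarray | None = None,
    window_ms: float = 60_000.0,
    min_window_ms: float = 30_000.0,
) -> EvaluationReport:
    """Beat-wise and window-averaged absolute errors of a mode trend.

    ``l1_mean`` is the mean over beats of |mode - truth|; ``l1_min`` is
    the absolute difference of window means (non-overlapping windows
    anchored at the record start; a trailing partial window of at least
    ``min_window_ms`` counts), averaged over windows.  Normalized versions
    divide by the per-property range ``r`` (default: max - min of the
    truth trend) and express the result as a percentage.
    """
    mode = np.atleast_2d(np.asarray(mode, float).T).T
    truth = np.atleast_2d(np.asarray(truth, float).T).T
    rr = np.asarray(rr, dtype=float)
    if mode.shape != truth.shape or mode.shape[0] != rr.size:
        raise ValueError("mode, truth and rr must cover the same beats")
    p = mode.shape[1]
    l1 = np.mean(np.abs(mode - truth), axis=0)

    start = 0.0
    bounds = []
    end = rr[-1]
    while start < end:
        stop = start + window_ms
        if stop > end:
            if end - start >= min_window_ms and bounds:
                bounds.append((start, end + 1.0))
            elif not bounds:
                bounds.append((start, end + 1.0))  # short record: single window
            break
        bounds.append((start, stop))
        start = stop
    win_errs = []
    for lo, hi in bounds:
        sel = (rr > lo) & (rr <= hi) if lo > 0 else (rr >= lo) & (rr <= hi)
        if not sel.any():
            continue
        win_errs.append(np.abs(mode[sel].mean(axis=0) - truth[sel].mean(axis=0)))
    l1_min = np.mean(win_errs, axis=0) if win_errs else np.full(p, np.nan)

    if normalization_range is None:
        r = truth.max(axis=0) - truth.min(axis=0)
    else:
        r = np.asarray(normalization_range, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        l1_norm = np.where(r > 0, l1 / r * 100.0, np.nan)
        l1_min_norm = np.where(r > 0, l1_min / r * 100.0, np.nan)
    return EvaluationReport(
        l1_mean=l1, l1_min=l1_min, l1_norm=l1_norm, l1_min_norm=l1_min_norm,
        cr95=None, normalization_range=r,
    )


def cr95_coverage(samples: np.ndarray, truth: np.ndarray,
                  lo_pct: float = 2.5, hi_pct: float = 97.5) -> np.ndarray:
    """Percent of beats where the truth lies inside the [2.5, 97.5] percentile band.

    ``samples``: (M, K) or (M, K, P); percentiles use linear interpolation
    between order statistics.
    """
    arr = np.asarray(samples, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    tr = np.atleast_2d(np.asarray(truth, float).T).T
    lo = np.percentile(arr, lo_pct, axis=0)
    hi = np.percentile(arr, hi_pct, axis=0)
    cov = ((tr >= lo) & (tr <= hi)).mean(axis=0) * 100.0
    return float(cov[0]) if squeeze else cov


def bland_altman(a: np.ndarray, b: np.ndarray) -> dict:
    """Bland-Altman agreement between two aligned trends.

    Returns per-beat (mean, difference) pairs, the bias (mean difference)
    and the limits of agreement ``bias +/- 1.96 * SD``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("trends must be aligned on the same beats")
    diff = a - b
    mean = (a + b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=0))
    return {
        "mean": mean,
        "difference": diff,
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }


@dataclass
class TiltSummary:
    """Phase means per patient/property plus paired one-sided test results."""

    phase_means: pd.DataFrame  # columns: patient, property, supine, hdt, hut
    tests: pd.DataFrame  # columns: property, comparison, p_value, n_decrease, n, shapiro_p


def tilt_analysis(
    mode_trends: dict,
    phase_bounds: dict,
    rr_times: dict,
    alternative: str = "greater",
) -> TiltSummary:
    """Tilt-phase analysis over patients.

    ``mode_trends[patient]`` is a (K, P) mode trend, ``rr_times[patient]``
    the matching beat times, ``phase_bounds[patient]`` a mapping
    ``{"supine": (t0, t1), "hdt": (t0, t1), "hut": (t0, t1)}`` with
    disjoint, time-ordered intervals.  Per property, a paired one-sided
    Wilcoxon signed-rank test compares supine against each tilt phase
    (``alternative="greater"`` tests for a decrease under tilt), with a
    Shapiro-Wilk normality p-value reported alongside.  Patients with an
    empty phase are excluded (logged).
    """
    rows = []
    for patient, trend in mode_trends.items():
        trend = np.atleast_2d(np.asarray(trend, float).T).T
        times = np.asarray(rr_times[patient], dtype=float)
        bounds = phase_bounds[patient]
        order = [bounds[ph][0] for ph in ("supine", "hdt", "hut")]
        if not (order[0] < order[1] < order[2]):
            raise ValueError(f"phases must be time-ordered for patient {patient}")
        means = {}
        ok = True
        for ph in ("supine", "hdt", "hut"):
            lo, hi = bounds[ph]
            sel = (times >= lo) & (times < hi)
            if not sel.any():
                logger.warning("patient %s has no beats in phase %s; excluded", patient, ph)
                ok = False
                break
            means[ph] = trend[sel].mean(axis=0)
        if not ok:
            continue
        for j in range(trend.shape[1]):
            rows.append(
                {
                    "patient": patient,
                    "property": PROPERTY_NAMES[j] if j < 4 else f"p{j}",
                    "supine": means["supine"][j],
                    "hdt": means["hdt"][j],
                    "hut": means["hut"][j],
                }
            )
    phase_means = pd.DataFrame(rows)
    tests = []
    if len(phase_means):
        for prop, grp in phase_means.groupby("property", sort=False):
            for comp in ("hdt", "hut"):
                sup = grp["supine"].to_numpy()
                other = grp[comp].to_numpy()
                d = sup - other
                if np.allclose(d, 0):
                    pval = 1.0
                else:
                    pval = float(stats.wilcoxon(sup, other, alternative=alternative).pvalue)
                shap = float(stats.shapiro(d).pvalue) if len(d) >= 3 and not np.allclose(d, d[0]) else np.nan
                tests.append(
                    {
                        "property": prop,
                        "comparison": f"supine_vs_{comp}",
                        "p_value": pval,
                        "n_decrease": int((d > 0).sum()),
                        "n": len(d),
                        "shapiro_p": shap,
                    }
                )
    return TiltSummary(phase_means=phase_means, tests=pd.DataFrame(tests))
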