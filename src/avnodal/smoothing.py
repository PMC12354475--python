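"""Forward-filtering backward-sampling (FFBS) smoother.

Given a completed filter run, draw whole trajectories of particle indices
from the smoothing distribution: the final index is sampled proportional
to the final filter weights, and going backwards each weight is tilted by
the Gaussian transition density that the selected next-step particle
originated from the candidate,

    w_hat[k, j] = w[k, j] * N(theta[k+1, x(k+1)] | theta[k, j], Sigma),

with Sigma the filter's propagation covariance (diagonal here).  Each
index trajectory yields a trajectory of parameters theta and, through the
per-particle beat records, of conduction properties phi -- the posterior
samples all reported summaries are built from.

Trajectories are drawn in a vectorized sweep: per backward step the
transition log-densities are computed once per *unique* selected
next-step particle (a matrix product over the sigma-scaled coordinates),
which is exactly equivalent to the naive per-trajectory recomputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .filters import FilterResult

logger = logging.getLogger(__name__)

__all__ = ["SmoothedPosterior", "backward_weights", "sample_trajectory", "run_ffbs"]


@dataclass
class SmoothedPosterior:
    """M sampled trajectories of theta and phi over all K beats."""

    thetas: np.ndarray  # (M, K, 12)
    phis: np.ndarray  # (M, K, 4)
    indices: np.ndarray  # (M, K) particle indices

    @property
    def n_trajectories(self) -> int:
        return self.thetas.shape[0]

    @property
    def n_beats(self) -> int:
        return self.thetas.shape[1]

    def to_frame(self):
        import pandas as pd

        from .model import THETA_COLUMNS

        m, k, _ = self.thetas.shape
        df = pd.DataFrame(
            self.thetas.reshape(m * k, 12), columns=THETA_COLUMNS
        )
        for i, name in enumerate(["r_fp", "r_sp", "d_fp", "d_sp"]):
            df[name] = self.phis.reshape(m * k, 4)[:, i]
        df.insert(0, "beat", np.tile(np.arange(k), m))
        df.insert(0, "trajectory", np.repeat(np.arange(m), k))
        return df


def _log_transition(theta_next: np.ndarray, thetas_k: np.ndarray, std: np.ndarray) -> np.ndarray:
    """Log N(theta_next | thetas_k[j], diag(std^2)) up to a constant, for all j.

    Parameters with zero step size contribute a point mass: 0 where the
    coordinates agree exactly, -inf otherwise (pseudo-density on the
    support of a singular Sigma).
    """
    pos = std > 0
    diff = theta_next[pos] - thetas_k[:, pos]
    out = -0.5 * np.sum((diff / std[pos]) ** 2, axis=1)
    if not pos.all():
        exact = np.all(theta_next[~pos] == thetas_k[:, ~pos], axis=1)
        out = np.where(exact, out, -np.inf)
    return out


def backward_weights(
    weights_k: np.ndarray,
    thetas_k: np.ndarray,
    theta_next_selected: np.ndarray,
    std: np.ndarray,
) -> np.ndarray:
    """Backward-tilted, normalized weights at step k given the selected
    particle at step k+1."""
    w = np.asarray(weights_k, dtype=float)
    log_t = _log_transition(np.asarray(theta_next_selected, float),
                            np.atleast_2d(np.asarray(thetas_k, float)),
                            np.asarray(std, float))
    with np.errstate(divide="ignore"):
        log_w = np.log(w) + log_t
    finite = np.isfinite(log_w)
    if not finite.any():
        # singular-Sigma pseudo-density wiped everything: fall back to the
        # filter weights (logged; only reachable with a mis-specified Sigma)
        logger.warning("backward weights degenerate; falling back to filter weights")
        return w / w.sum()
    out = np.where(finite, np.exp(log_w - log_w[finite].max()), 0.0)
    return out / out.sum()


def sample_trajectory(
    result: FilterResult, rng: np.random.Generator, std: np.ndarray | None = None
) -> np.ndarray:
    """Draw a single backward index trajectory (length K)."""
    post = run_ffbs(result, 1, rng, std=std)
    return post.indices[0]


@njit(cache=True)
def _sample_grouped(log_w, group_of_m, uniforms, out_idx):
    """For each trajectory m, draw an index from softmax(log_w[group_of_m[m]]).

    Shares one cumulative distribution per unique group row.
    """
    n_groups, n = log_w.shape
    m_total = group_of_m.shape[0]
    cdf = np.empty(n)
    for g in range(n_groups):
        mx = -np.inf
        for j in range(n):
            if log_w[g, j] > mx:
                mx = log_w[g, j]
        tot = 0.0
        for j in range(n):
            v = np.exp(log_w[g, j] - mx) if log_w[g, j] > -np.inf else 0.0
            tot += v
            cdf[j] = tot
        for m in range(m_total):
            if group_of_m[m] == g:
                u = uniforms[m] * tot
                lo, hi = 0, n - 1
                while lo < hi:
                    mid = (lo + hi) >> 1
                    if cdf[mid] < u:
                        lo = mid + 1
                    else:
                        hi = mid
                out_idx[m] = lo


def run_ffbs(
    result: FilterResult,
    n_trajectories: int,
    rng: np.random.Generator,
    std: np.ndarray | None = None,
) -> SmoothedPosterior:
    """Draw ``n_trajectories`` independent smoothing trajectories.

    ``std`` defaults to the filter's propagation standard deviations (the
    diagonal of Sigma).
    """
    m = int(n_trajectories)
    if m < 1:
        raise ValueError("need at least one trajectory")
    std = result.config.propagation_std if std is None else np.asarray(std, float)
    k_total, n, _ = result.thetas.shape
    indices = np.empty((m, k_total), dtype=np.int64)

    w_last = result.weights[-1]
    cdf = np.cumsum(w_last / w_last.sum())
    indices[:, -1] = np.searchsorted(cdf, rng.random(m)).clip(0, n - 1)

    pos = std > 0
    sstd = std[pos]
    for k in range(k_total - 2, -1, -1):
        nxt = indices[:, k + 1]
        uniq, group_of_m = np.unique(nxt, return_inverse=True)
        theta_next = result.thetas[k + 1][uniq]  # (U, 12)
        thetas_k = result.thetas[k]  # (N, 12)
        a = theta_next[:, pos] / sstd
        b = thetas_k[:, pos] / sstd
        # -0.5 * ||a_u - b_j||^2 expanded via a GEMM
        log_t = a @ b.T
        log_t -= 0.5 * np.sum(a * a, axis=1)[:, None]
        log_t -= 0.5 * np.sum(b * b, axis=1)[None, :]
        if not pos.all():
            fixed_next = theta_next[:, ~pos]
            fixed_k = thetas_k[:, ~pos]
            mism = (fixed_next[:, None, :] != fixed_k[None, :, :]).any(axis=2)
            log_t[mism] = -np.inf
        with np.errstate(divide="ignore"):
            log_w = np.log(result.weights[k])[None, :] + log_t
        # guard rows wiped out by the singular-Sigma point mass
        dead = ~np.isfinite(log_w).any(axis=1)
        if dead.any():
            with np.errstate(divide="ignore"):
                log_w[dead] = np.log(result.weights[k])[None, :]
        out_idx = np.empty(m, dtype=np.int64)
        _sample_grouped(log_w, group_of_m.astype(np.int64), rng.random(m), out_idx)
        indices[:, k] = out_idx

    thetas = result.thetas[np.arange(k_total)[None, :], indices]
    phis = result.phis[np.arange(k_total)[None, :], indices]
    return SmoothedPosterior(thetas=thetas, phis=phis, indices=indices)
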