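"""File-format plumbing: series CSVs, configuration, run manifests.

All timestamps are serialized in ms with six decimal places so that
event-time arithmetic survives a round trip exactly at the precision the
simulator operates in.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atrial import AASeries, FWaveFeatures
from .filters import FilterConfig, FilterResult, PriorBounds
from .model import THETA_COLUMNS

__all__ = [
    "read_series",
    "write_series",
    "read_theta_trend",
    "write_theta_trend",
    "read_features",
    "write_features",
    "load_config",
    "dump_config",
    "write_manifest",
    "save_filter_result",
]

_FLOAT_FMT = "%.6f"


def write_series(times, path, kind: str) -> None:
    """Write a timestamp series as a single-column CSV (header names the kind)."""
    if kind not in ("aa_ms", "rr_ms"):
        raise ValueError("kind must be 'aa_ms' or 'rr_ms'")
    times = np.asarray(getattr(times, "activation_times", times), dtype=float)
    pd.DataFrame({kind: times}).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series(path, kind: str) -> np.ndarray:
    """Read a timestamp series; rejects non-monotone input."""
    df = pd.read_csv(path)
    if kind not in df.columns:
        raise ValueError(f"{path}: expected a column named {kind!r}, found {list(df.columns)}")
    t = df[kind].to_numpy(float)
    if t.size == 0:
        raise ValueError(f"{path}: empty series")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: series must be strictly increasing")
    return t


def write_theta_trend(trend: np.ndarray, path) -> None:
    pd.DataFrame(np.atleast_2d(trend), columns=THETA_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_theta_trend(path) -> np.ndarray:
    df = pd.read_csv(path)
    missing = [c for c in THETA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing theta columns {missing}")
    return df[THETA_COLUMNS].to_numpy(float)


def write_features(features: FWaveFeatures, path) -> None:
    features.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_features(path) -> FWaveFeatures:
    return FWaveFeatures.from_frame(pd.read_csv(path))


def load_config(path) -> FilterConfig:
    """Load a FilterConfig from YAML/JSON; omitted keys take the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "prior" in raw:
        raw["prior"] = PriorBounds(
            lower=np.asarray(raw["prior"]["lower"], float),
            upper=np.asarray(raw["prior"]["upper"], float),
        )
    if "propagation_std" in raw and raw["propagation_std"] is not None:
        raw["propagation_std"] = np.asarray(raw["propagation_std"], float)
    return FilterConfig(**raw)


def dump_config(config: FilterConfig, path) -> None:
    d = asdict(config)
    d["prior"] = {"lower": config.prior.lower.tolist(), "upper": config.prior.upper.tolist()}
    d["propagation_std"] = config.propagation_std.tolist()
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(directory, config: FilterConfig | None, seed: int, inputs: dict) -> None:
    """Run manifest: config snapshot, seed, code version, input digests."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {name: _digest(p) for name, p in inputs.items()},
    }
    if config is not None:
        manifest["config"] = {
            "n_particles": config.n_particles,
            "n_ecg_copies": config.n_ecg_copies,
            "sigma_w": config.sigma_w,
            "propagation_std": config.propagation_std.tolist(),
            "prior_lower": config.prior.lower.tolist(),
            "prior_upper": config.prior.upper.tolist(),
            "horizon_ms": config.horizon_ms,
            "resampling_scheme": config.resampling_scheme,
            "n_per_path": config.n_per_path,
        }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def save_filter_result(result: FilterResult, directory) -> None:
    """Per-beat tabular export of a filter run (particles, weights, beats, phi)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for k in range(result.n_beats):
        df = pd.DataFrame(result.thetas[k], columns=THETA_COLUMNS)
        df["weight"] = result.weights[k]
        df["vhat_ms"] = result.vhats[k]
        for i, name in enumerate(["r_fp", "r_sp", "d_fp", "d_sp"]):
            df[name] = result.phis[k][:, i]
        df.to_csv(d / f"beat_{k:05d}.csv", index=False, float_format=_FLOAT_FMT)
    summary = pd.DataFrame(
        {"beat": np.arange(result.n_beats), "v_obs_ms": result.rr,
         "ess": result.ess, "degenerate": result.degenerate}
    )
    summary.to_csv(d / "summary.csv", index=False, float_format=_FLOAT_FMT)
    write_manifest(d, result.config, result.config.seed, {})
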