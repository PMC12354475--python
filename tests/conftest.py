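"""Shared fixtures and the independent brute-force oracle simulator."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from avnodal.benchmark import BenchmarkSpec, generate_benchmark
from avnodal.model import CouplingNodeConfig, ModelParameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def brute_force_beats(
    theta_vec,
    aa_times,
    coupling_refractory,
    coupling_delay,
    n_per_path,
    t_end,
    dt=0.01,
):
    """Fixed-step brute-force simulator of the dual-pathway network.

    Independent of the event-driven implementations: keeps an unsorted
    list of pending impulses and scans time on a ``dt`` grid, processing
    due impulses in (exact arrival time, node index, insertion order).
    Delay arithmetic is exact, so beat times agree with the event-driven
    simulator to floating-point precision.
    """
    th = np.asarray(theta_vec, dtype=float)
    n = n_per_path
    cpl = 2 * n
    pending = []  # (time, node, counter)
    counter = 0
    for t in aa_times:
        pending.append((float(t), 0, counter))
        counter += 1
        pending.append((float(t), n, counter))
        counter += 1
    rt = np.zeros(2 * n + 1)
    beats = []
    t_grid = 0.0
    while t_grid <= t_end + dt:
        due = sorted([e for e in pending if e[0] <= t_grid], key=lambda e: (e[0], e[1], e[2]))
        if not due:
            if not pending:
                break
            # advance the grid to the bin containing the next pending impulse
            nxt = min(e[0] for e in pending)
            if nxt > t_end:
                break
            t_grid = np.floor(nxt / dt) * dt + dt
            continue
        for ev in due:
            pending.remove(ev)
            t, node, _ = ev
            if t - rt[node] < 0:
                continue  # refractory: blocked
            t_tilde = t - rt[node]
            if node == cpl:
                rt[cpl] = t + coupling_refractory
                beats.append(t + coupling_delay)
                continue
            if node < n:
                r = th[0] + th[1] * (1 - np.exp(-t_tilde / th[2]))
                d = th[6] + th[7] * np.exp(-t_tilde / th[8])
            else:
                r = th[3] + th[4] * (1 - np.exp(-t_tilde / th[5]))
                d = th[9] + th[10] * np.exp(-t_tilde / th[11])
            rt[node] = t + r
            nxt_node = cpl if node in (n - 1, 2 * n - 1) else node + 1
            pending.append((t + d, nxt_node, counter))
            counter += 1
        t_grid += dt
    return np.asarray(beats)


@pytest.fixture(scope="session")
def oracle():
    return brute_force_beats


@pytest.fixture(scope="session")
def toy_theta():
    """An ordering-consistent parameter vector with distinct pathways."""
    return np.array([300.0, 400.0, 120.0, 250.0, 300.0, 100.0,
                     5.0, 10.0, 150.0, 30.0, 25.0, 150.0])


@pytest.fixture(scope="session")
def toy_params(toy_theta):
    return ModelParameters.from_vector(toy_theta)


@pytest.fixture(scope="session")
def toy_coupling():
    return CouplingNodeConfig(refractory=250.0, delay=60.0)


@pytest.fixture(scope="session")
def bench_record():
    """One 30 s constant-truth benchmark record shared across tests."""
    spec = BenchmarkSpec(n_records=1, duration_s=30.0, trend_dynamics="constant", seed=11)
    return generate_benchmark(spec)[0]
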