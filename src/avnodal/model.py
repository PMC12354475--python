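"""Event-driven network model of the dual-pathway AV node.

The AV node is represented as two chains of excitable nodes -- the fast
pathway (FP) and the slow pathway (SP), ten nodes each by default --
converging on a single coupling node that represents the Bundle of His /
Purkinje junction and emits ventricular activations.  Atrial impulses enter
at the first node of both pathways simultaneously and propagate node to
node in an event-driven fashion.  Each node is either refractory (blocks
the impulse) or excitable (transmits it with a conduction delay and then
becomes refractory).

For node ``i`` and incoming impulse ``n`` the refractory period and the
per-node conduction delay recover exponentially with the preceding
diastolic interval ``t~``::

    R(t~) = R_min + dR * (1 - exp(-t~ / tau_R))
    D(t~) = D_min + dD * exp(-t~ / tau_D)
    t~    = t_arrival - (t_prev + R_prev)        # <0 means refractory

Each pathway carries six parameters (three for R, three for D), so the
full model has 12 degrees of freedom (the coupling node's refractory
period and its 60 ms delay are fixed per dataset, not estimated).

Per inter-beat interval the model is summarized by the conduction
properties ``phi = [R_FP, R_SP, D_FP, D_SP]``: the medians of the realized
R and per-node D values in the interval, with D multiplied by the number
of nodes in the pathway to give the whole-pathway delay.

This module holds the readable reference implementation (a binary-heap
event queue in pure Python).  The particle filters use a numba batch
engine (:mod:`avnodal._engine`) implementing the identical contract.
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PathwayParameters",
    "ModelParameters",
    "CouplingNodeConfig",
    "ImpulseEvent",
    "ModelState",
    "BeatRecord",
    "ConductionProperties",
    "AVNodeNetwork",
    "refractory_period",
    "conduction_delay",
    "diastolic_interval",
    "simulate_until_beat",
    "simulate_rr_series",
    "summarize_properties",
    "THETA_COLUMNS",
]

#: Column order of the flat 12-vector serialization of ModelParameters.
THETA_COLUMNS = [
    "r_min_fp", "delta_r_fp", "tau_r_fp",
    "r_min_sp", "delta_r_sp", "tau_r_sp",
    "d_min_fp", "delta_d_fp", "tau_d_fp",
    "d_min_sp", "delta_d_sp", "tau_d_sp",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its physical constraints."""


class CorruptedStateError(RuntimeError):
    """The simulator state references a node outside the network."""


@dataclass(frozen=True)
class PathwayParameters:
    """Six parameters of one pathway: R_min, dR, tau_R, D_min (per node), dD, tau_D.

    All values in ms; ``tau_r`` and ``tau_d`` must be strictly positive.
    """

    r_min: float
    delta_r: float
    tau_r: float
    d_min: float
    delta_d: float
    tau_d: float

    def __post_init__(self) -> None:
        vals = (self.r_min, self.delta_r, self.tau_r, self.d_min, self.delta_d, self.tau_d)
        if not all(math.isfinite(v) and v >= 0 for v in vals):
            raise InvalidParameterError(f"pathway parameters must be finite and >= 0, got {vals}")
        if self.tau_r <= 0 or self.tau_d <= 0:
            raise InvalidParameterError("tau_r and tau_d must be > 0")


@dataclass(frozen=True)
class ModelParameters:
    """The 12 AV-node model parameters: one :class:`PathwayParameters` per pathway."""

    fp: PathwayParameters
    sp: PathwayParameters

    def to_vector(self) -> np.ndarray:
        """Flat ordered vector, see :data:`THETA_COLUMNS`."""
        return np.array(
            [
                self.fp.r_min, self.fp.delta_r, self.fp.tau_r,
                self.sp.r_min, self.sp.delta_r, self.sp.tau_r,
                self.fp.d_min, self.fp.delta_d, self.fp.tau_d,
                self.sp.d_min, self.sp.delta_d, self.sp.tau_d,
            ],
            dtype=float,
        )

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "ModelParameters":
        v = np.asarray(v, dtype=float)
        if v.shape != (12,):
            raise InvalidParameterError(f"expected a 12-vector, got shape {v.shape}")
        fp = PathwayParameters(v[0], v[1], v[2], v[6], v[7], v[8])
        sp = PathwayParameters(v[3], v[4], v[5], v[9], v[10], v[11])
        return cls(fp=fp, sp=sp)


@dataclass(frozen=True)
class CouplingNodeConfig:
    """Fixed refractory period and conduction delay of the coupling node.

    The delay is fixed at 60 ms; the refractory period is set per dataset to
    the shortest observed RR interval minus 50 ms (see
    :func:`coupling_from_rr`), and is overridable for toy configurations.
    """

    refractory: float = 250.0
    delay: float = 60.0

    def __post_init__(self) -> None:
        if self.refractory < 0 or self.delay < 0:
            raise InvalidParameterError("coupling refractory and delay must be >= 0")


def coupling_from_rr(rr_times: Sequence[float], margin: float = 50.0, delay: float = 60.0) -> CouplingNodeConfig:
    """Coupling node with refractory period = shortest observed RR interval - margin."""
    rr = np.diff(np.asarray(rr_times, dtype=float))
    if rr.size == 0:
        return CouplingNodeConfig(refractory=0.0, delay=delay)
    return CouplingNodeConfig(refractory=max(0.0, float(rr.min()) - margin), delay=delay)


@dataclass(frozen=True, order=True)
class ImpulseEvent:
    """A pending impulse: (arrival time, node index, insertion sequence).

    Ordering is (time, node, seq): simultaneous events are processed in
    ascending node index, then first-in first-out.
    """

    arrival_time: float
    node_index: int
    seq: int = 0
    origin: float = field(default=0.0, compare=False)  # atrial impulse that spawned this


@dataclass
class BeatRecord:
    """Realized (R, D) node values since the previous ventricular beat.

    ``node_history`` holds tuples ``(node_index, R, D)``; ``pathway`` is 0
    for FP and 1 for SP entries (parallel list).
    """

    beat_time: float
    node_history: list = field(default_factory=list)  # (node_index, R, D)
    pathway: list = field(default_factory=list)  # 0 = FP, 1 = SP


@dataclass(frozen=True)
class ConductionProperties:
    """Per-beat summary phi = [R_FP, R_SP, D_FP, D_SP] (whole-pathway delays, ms)."""

    r_fp: float
    r_sp: float
    d_fp: float
    d_sp: float

    def to_vector(self) -> np.ndarray:
        return np.array([self.r_fp, self.r_sp, self.d_fp, self.d_sp], dtype=float)


# ---------------------------------------------------------------------------
# Recovery curves (Eqs. of the node dynamics)
# ---------------------------------------------------------------------------

def refractory_period(t_tilde: float, p: PathwayParameters) -> float:
    """Refractory period after a diastolic interval ``t_tilde``.

    ``R_min + dR * (1 - exp(-t_tilde / tau_R))`` -- nondecreasing in
    ``t_tilde`` for ``t_tilde >= 0``.
    """
    if p.tau_r <= 0:
        raise InvalidParameterError("tau_r must be > 0")
    return p.r_min + p.delta_r * (1.0 - math.exp(-t_tilde / p.tau_r))


def conduction_delay(t_tilde: float, p: PathwayParameters) -> float:
    """Per-node conduction delay after a diastolic interval ``t_tilde``.

    ``D_min + dD * exp(-t_tilde / tau_D)`` -- nonincreasing in ``t_tilde``.
    """
    if p.tau_d <= 0:
        raise InvalidParameterError("tau_d must be > 0")
    return p.d_min + p.delta_d * math.exp(-t_tilde / p.tau_d)


def diastolic_interval(t_now: float, t_prev: float, r_prev: float) -> float:
    """``t_now - (t_prev + r_prev)``; negative means the node is refractory."""
    return t_now - (t_prev + r_prev)


# ---------------------------------------------------------------------------
# Event-driven simulator (pure-Python reference implementation)
# ---------------------------------------------------------------------------

class AVNodeNetwork:
    """Event-driven simulator of the dual-pathway network.

    Node indexing with ``n`` nodes per pathway: FP nodes ``0..n-1`` (entry
    0), SP nodes ``n..2n-1`` (entry ``n``), coupling node ``2n``.  Impulses
    travel antegradely along each chain into the coupling node, which emits
    a ventricular activation ``delay`` ms after transmitting.

    The repolarization-time vector ``rt`` stores, per node, the end of its
    current refractory window (last conducted arrival + its refractory
    period); blocked impulses do not reset it.  The first impulse at a node
    sees ``rt = 0``, so its diastolic interval equals its arrival time.
    """

    def __init__(
        self,
        params: ModelParameters,
        coupling: CouplingNodeConfig,
        n_per_path: int = 10,
    ) -> None:
        if n_per_path < 1:
            raise InvalidParameterError("n_per_path must be >= 1")
        self.params = params
        self.coupling = coupling
        self.n = int(n_per_path)
        self.rt = np.zeros(2 * self.n + 1, dtype=float)
        self.queue: list[tuple[float, int, int, float]] = []  # (t, node, seq, origin)
        self._seq = 0
        # history of (node, R, D) + pathway id since the last emitted beat
        self._hist_nodes: list[tuple[int, float, float]] = []
        self._hist_path: list[int] = []

    # -- queue management ---------------------------------------------------

    def inject_atrial(self, times: Iterable[float]) -> None:
        """Insert atrial impulses: each enters FP entry then SP entry (tie order)."""
        for t in times:
            t = float(t)
            if t < 0:
                raise CorruptedStateError(f"atrial impulse at negative time {t}")
            self._push(t, 0, t)
            self._push(t, self.n, t)

    def _push(self, t: float, node: int, origin: float) -> None:
        heapq.heappush(self.queue, (t, node, self._seq, origin))
        self._seq += 1

    def next_event_time(self) -> float:
        return self.queue[0][0] if self.queue else math.inf

    # -- dynamics -----------------------------------------------------------

    def _pathway_of(self, node: int) -> PathwayParameters:
        return self.params.fp if node < self.n else self.params.sp

    def process_next_event(self, params: ModelParameters | None = None):
        """Pop and process the earliest impulse; return the emitted beat time or None.

        ``params`` overrides the network parameters for this event (used by
        the two-parameter re-simulation of the ECG filter).
        """
        if not self.queue:
            raise CorruptedStateError("event queue is empty")
        t, node, _seq, origin = heapq.heappop(self.queue)
        if node < 0 or node > 2 * self.n:
            raise CorruptedStateError(f"node index {node} outside the network")
        p_all = params if params is not None else self.params
        t_tilde = t - self.rt[node]
        if t_tilde < 0:  # refractory: impulse blocked, rt untouched
            return None
        if node == 2 * self.n:  # coupling node -> ventricular activation
            self.rt[node] = t + self.coupling.refractory
            return t + self.coupling.delay, origin
        p = p_all.fp if node < self.n else p_all.sp
        r = refractory_period(t_tilde, p)
        d = conduction_delay(t_tilde, p)
        self.rt[node] = t + r
        nxt = 2 * self.n if node in (self.n - 1, 2 * self.n - 1) else node + 1
        self._push(t + d, nxt, origin)
        self._hist_nodes.append((node, r, d))
        self._hist_path.append(0 if node < self.n else 1)
        return None

    def run_until_beat(
        self,
        horizon: float = math.inf,
        params_after: ModelParameters | None = None,
        switch_time: float | None = None,
    ):
        """Run until the next ventricular activation; return (beat, origin) or None.

        Events at times ``>= switch_time`` use ``params_after``.  The
        returned state (``self``) is the state at ventricular activation
        time, ready to resume.  ``None`` means no beat within ``horizon``
        (the caller assigns zero weight; not an exception).
        """
        while self.queue and self.queue[0][0] <= horizon:
            t = self.queue[0][0]
            p = None
            if params_after is not None and switch_time is not None and t >= switch_time:
                p = params_after
            out = self.process_next_event(params=p)
            if out is not None:
                return out
        return None

    def take_beat_record(self, beat_time: float) -> BeatRecord:
        """Consume the node history accumulated since the previous beat."""
        rec = BeatRecord(beat_time=beat_time, node_history=self._hist_nodes, pathway=self._hist_path)
        self._hist_nodes = []
        self._hist_path = []
        return rec


#: Backwards-compatible functional alias used in a few call sites/tests.
def simulate_until_beat(
    network: AVNodeNetwork,
    horizon: float = math.inf,
    params_after: ModelParameters | None = None,
    switch_time: float | None = None,
):
    """Functional wrapper over :meth:`AVNodeNetwork.run_until_beat`."""
    return network.run_until_beat(horizon=horizon, params_after=params_after, switch_time=switch_time)


# ---------------------------------------------------------------------------
# Per-beat summarization
# ---------------------------------------------------------------------------

def summarize_properties(
    history: BeatRecord,
    params: ModelParameters,
    n_per_path: int = 10,
    previous: ConductionProperties | None = None,
    elapsed_diastole: tuple[float, float] | None = None,
) -> ConductionProperties:
    """Summarize an inter-beat interval into phi = [R_FP, R_SP, D_FP, D_SP].

    Per pathway, R is the median of the realized node refractory periods in
    the interval and D is ``n_per_path`` times the median of the realized
    per-node delays.  A pathway with no realized impulses in the interval
    carries forward its most recent value (``previous``); with no previous
    value either, the recovery curves are evaluated at the elapsed
    diastolic interval of the pathway's entry node.
    """
    vals: dict[int, tuple[float, float]] = {}
    for path in (0, 1):
        rs = [r for (_, r, _), pw in zip(history.node_history, history.pathway) if pw == path]
        ds = [d for (_, _, d), pw in zip(history.node_history, history.pathway) if pw == path]
        if rs:
            vals[path] = (float(np.median(rs)), float(np.median(ds)) * n_per_path)
        elif previous is not None:
            prev = previous.to_vector()
            vals[path] = (prev[path], prev[2 + path])
        else:
            tt = 0.0 if elapsed_diastole is None else max(0.0, elapsed_diastole[path])
            p = params.fp if path == 0 else params.sp
            vals[path] = (refractory_period(tt, p), conduction_delay(tt, p) * n_per_path)
    return ConductionProperties(r_fp=vals[0][0], r_sp=vals[1][0], d_fp=vals[0][1], d_sp=vals[1][1])


# ---------------------------------------------------------------------------
# Whole-record simulation with a per-beat parameter trend
# ---------------------------------------------------------------------------

def simulate_rr_series(
    theta_trend: Sequence[ModelParameters],
    aa_times: Sequence[float],
    coupling: CouplingNodeConfig,
    n_per_path: int = 10,
    horizon_pad: float = 5000.0,
) -> tuple[np.ndarray, list[ConductionProperties]]:
    """Simulate a ventricular beat series driven by an atrial series.

    ``theta_trend[k]`` governs the interval producing beat ``k``; if more
    beats occur than the trend covers, the last entry is held.  Returns the
    beat times and the per-beat ground-truth conduction properties
    (computed by :func:`summarize_properties` over each inter-beat
    interval, with carry-forward for silent pathways).
    """
    aa = np.asarray(aa_times, dtype=float)
    if aa.size == 0:
        raise ValueError("empty atrial series")
    if np.any(np.diff(aa) <= 0):
        raise ValueError("atrial series must be strictly increasing")
    trend = list(theta_trend)
    if not trend:
        raise ValueError("empty parameter trend")
    horizon = float(aa[-1]) + horizon_pad

    net = AVNodeNetwork(trend[0], coupling, n_per_path=n_per_path)
    net.inject_atrial(aa)
    beats: list[float] = []
    phis: list[ConductionProperties] = []
    prev_phi: ConductionProperties | None = None
    k = 0
    while True:
        theta_k = trend[min(k, len(trend) - 1)]
        net.params = theta_k
        out = net.run_until_beat(horizon=horizon)
        if out is None:
            if not beats:
                warnings.warn("atrial series exhausted before any ventricular beat")
            break
        beat, _origin = out
        rec = net.take_beat_record(beat)
        elapsed = (beat - net.rt[0], beat - net.rt[net.n])
        phi = summarize_properties(
            rec, theta_k, n_per_path=n_per_path, previous=prev_phi, elapsed_diastole=elapsed
        )
        beats.append(beat)
        phis.append(phi)
        prev_phi = phi
        k += 1
    if aa[-1] > (beats[-1] if beats else 0.0) + horizon_pad:
        warnings.warn("simulation truncated: no further beats within horizon")
    return np.asarray(beats, dtype=float), phis
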