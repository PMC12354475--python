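"""Numba batch engine for the event-driven AV-node network.

Implements the same contract as :class:`avnodal.model.AVNodeNetwork`
(node chains, blocking rule, tie order (time, node, FIFO), coupling node)
on flat arrays, so that the particle filters can advance tens of
thousands of independent model states per observed beat.

Per-particle state:
  ``rt``        -- (2n+1,) repolarization times
  ``heap_*``    -- binary-heap arrays of pending *internal* events
  ``aa_ptr``    -- index of the next atrial impulse to feed

Atrial impulses are fed lazily from a shared (or per-particle) series,
which keeps the heap small and makes "state at time t" snapshots natural:
the heap never holds un-fed future atrial impulses.

Status codes returned by :func:`run_engine`:
  ``>= 1`` number of beats emitted (stopped at ``max_beats``)
  ``0``    no beat before the horizon / queue exhausted
  ``-1``   heap or record capacity overflow (state corrupt, caller must drop)
  ``-2``   snapshot stop reached (``stop_before``)
"""

from __future__ import annotations

import numpy as np
from numba import njit

HEAP_CAP = 128

# theta vector layout (see model.THETA_COLUMNS):
# 0 r_min_fp 1 delta_r_fp 2 tau_r_fp 3 r_min_sp 4 delta_r_sp 5 tau_r_sp
# 6 d_min_fp 7 delta_d_fp 8 tau_d_fp 9 d_min_sp 10 delta_d_sp 11 tau_d_sp


@njit(cache=True, inline="always")
def _less(t1, n1, s1, t2, n2, s2):
    if t1 != t2:
        return t1 < t2
    if n1 != n2:
        return n1 < n2
    return s1 < s2


@njit(cache=True)
def _heap_push(ht, hn, ho, hs, size, t, node, org, seq):
    if size >= ht.shape[0]:
        return -1
    i = size
    ht[i] = t
    hn[i] = node
    ho[i] = org
    hs[i] = seq
    while i > 0:
        p = (i - 1) >> 1
        if _less(ht[i], hn[i], hs[i], ht[p], hn[p], hs[p]):
            ht[i], ht[p] = ht[p], ht[i]
            hn[i], hn[p] = hn[p], hn[i]
            ho[i], ho[p] = ho[p], ho[i]
            hs[i], hs[p] = hs[p], hs[i]
            i = p
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(ht, hn, ho, hs, size):
    t = ht[0]
    node = hn[0]
    org = ho[0]
    size -= 1
    ht[0] = ht[size]
    hn[0] = hn[size]
    ho[0] = ho[size]
    hs[0] = hs[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        m = i
        if l < size and _less(ht[l], hn[l], hs[l], ht[m], hn[m], hs[m]):
            m = l
        if r < size and _less(ht[r], hn[r], hs[r], ht[m], hn[m], hs[m]):
            m = r
        if m == i:
            break
        ht[i], ht[m] = ht[m], ht[i]
        hn[i], hn[m] = hn[m], hn[i]
        ho[i], ho[m] = ho[m], ho[i]
        hs[i], hs[m] = hs[m], hs[i]
        i = m
    return t, node, org, size


@njit(cache=True)
def run_engine(
    theta_a,
    theta_b,
    switch_time,  # events at t >= switch_time use theta_b
    rt,
    ht, hn, ho, hs,
    heap_size,
    seq0,
    aa, aa_ptr,
    n_per_path,
    cpl_r, cpl_d,
    horizon,
    max_beats,
    stop_before,  # snapshot mode: stop before any event at t >= stop_before (inf = off)
    record_from,  # record conduction (t, path, R, D) for events at t >= record_from
    rec_t, rec_path, rec_r, rec_d,
    out_beats, out_origins,
):
    """Advance one particle; mutates state arrays in place.

    Returns ``(status, heap_size, seq, aa_ptr, n_rec)``.
    """
    n = n_per_path
    cpl = 2 * n
    seq = seq0
    n_beats = 0
    n_rec = 0
    n_aa = aa.shape[0]
    while True:
        t_at = aa[aa_ptr] if aa_ptr < n_aa else np.inf
        t_in = ht[0] if heap_size > 0 else np.inf
        t_next = t_at if t_at <= t_in else t_in
        if stop_before != np.inf and t_next >= stop_before:
            return -2, heap_size, seq, aa_ptr, n_rec
        if t_next > horizon or t_next == np.inf:
            return (n_beats if n_beats > 0 else 0), heap_size, seq, aa_ptr, n_rec
        if t_at <= t_in:
            # feed the next atrial impulse into both pathway entries
            heap_size = _heap_push(ht, hn, ho, hs, heap_size, t_at, 0, t_at, seq)
            if heap_size < 0:
                return -1, 0, seq, aa_ptr, n_rec
            seq += 1
            heap_size = _heap_push(ht, hn, ho, hs, heap_size, t_at, n, t_at, seq)
            if heap_size < 0:
                return -1, 0, seq, aa_ptr, n_rec
            seq += 1
            aa_ptr += 1
            continue
        t, node, org, heap_size = _heap_pop(ht, hn, ho, hs, heap_size)
        t_tilde = t - rt[node]
        if t_tilde < 0.0:
            continue  # refractory: blocked, rt untouched
        if node == cpl:
            rt[cpl] = t + cpl_r
            out_beats[n_beats] = t + cpl_d
            out_origins[n_beats] = org
            n_beats += 1
            if n_beats >= max_beats:
                return n_beats, heap_size, seq, aa_ptr, n_rec
            continue
        th = theta_a if t < switch_time else theta_b
        if node < n:
            path = 0
            r = th[0] + th[1] * (1.0 - np.exp(-t_tilde / th[2]))
            d = th[6] + th[7] * np.exp(-t_tilde / th[8])
        else:
            path = 1
            r = th[3] + th[4] * (1.0 - np.exp(-t_tilde / th[5]))
            d = th[9] + th[10] * np.exp(-t_tilde / th[11])
        rt[node] = t + r
        nxt = cpl if (node == n - 1 or node == 2 * n - 1) else node + 1
        heap_size = _heap_push(ht, hn, ho, hs, heap_size, t + d, nxt, org, seq)
        if heap_size < 0:
            return -1, 0, seq, aa_ptr, n_rec
        seq += 1
        if t >= record_from:
            if n_rec >= rec_t.shape[0]:
                return -1, heap_size, seq, aa_ptr, n_rec
            rec_t[n_rec] = t
            rec_path[n_rec] = path
            rec_r[n_rec] = r
            rec_d[n_rec] = d
            n_rec += 1


@njit(cache=True)
def _phi_from_records(rec_path, rec_r, rec_d, n_rec, phi_prev, theta, rt, vhat, n_per_path, out):
    """Medians of recorded (R, D) per pathway; carry-forward / recovery-curve fallback.

    ``out`` is a length-4 buffer [R_FP, R_SP, D_FP, D_SP]; D is the
    whole-pathway delay (per-node median times n_per_path).
    """
    for path in range(2):
        cnt = 0
        for i in range(n_rec):
            if rec_path[i] == path:
                cnt += 1
        if cnt > 0:
            rs = np.empty(cnt)
            ds = np.empty(cnt)
            j = 0
            for i in range(n_rec):
                if rec_path[i] == path:
                    rs[j] = rec_r[i]
                    ds[j] = rec_d[i]
                    j += 1
            out[path] = np.median(rs)
            out[2 + path] = np.median(ds) * n_per_path
        elif np.isfinite(phi_prev[path]):
            out[path] = phi_prev[path]
            out[2 + path] = phi_prev[2 + path]
        else:
            entry = 0 if path == 0 else n_per_path
            tt = vhat - rt[entry]
            if tt < 0.0:
                tt = 0.0
            if path == 0:
                out[path] = theta[0] + theta[1] * (1.0 - np.exp(-tt / theta[2]))
                out[2 + path] = (theta[6] + theta[7] * np.exp(-tt / theta[8])) * n_per_path
            else:
                out[path] = theta[3] + theta[4] * (1.0 - np.exp(-tt / theta[5]))
                out[2 + path] = (theta[9] + theta[10] * np.exp(-tt / theta[11])) * n_per_path


@njit(cache=True)
def egm_step_all(
    thetas,        # (N, 12) parameters for this step
    rts,           # (N, 2n+1) in/out
    hts, hns, hos, hss,  # (N, HEAP_CAP) in/out
    heap_sizes, seqs, aa_ptrs,  # (N,) in/out
    aa,            # shared observed atrial series
    n_per_path,
    cpl_r, cpl_d,
    horizon,
    phis_prev,     # (N, 4) previous phi per particle (nan if none)
    rec_cap,
    vhats,         # (N,) out
    phis,          # (N, 4) out
):
    """Advance every particle to its next ventricular beat (invasive-input filter).

    Particles with no beat before the horizon get ``vhat = nan`` (the
    caller assigns zero weight).
    """
    n_particles = thetas.shape[0]
    rec_t = np.empty(rec_cap)
    rec_r = np.empty(rec_cap)
    rec_d = np.empty(rec_cap)
    rec_path = np.empty(rec_cap, dtype=np.int8)
    out_beats = np.empty(1)
    out_origins = np.empty(1)
    for j in range(n_particles):
        status, hsz, seq, aptr, n_rec = run_engine(
            thetas[j], thetas[j], -np.inf,
            rts[j], hts[j], hns[j], hos[j], hss[j],
            heap_sizes[j], seqs[j], aa, aa_ptrs[j],
            n_per_path, cpl_r, cpl_d, horizon, 1,
            np.inf, -np.inf,
            rec_t, rec_path, rec_r, rec_d,
            out_beats, out_origins,
        )
        heap_sizes[j] = hsz
        seqs[j] = seq
        aa_ptrs[j] = aptr
        if status == 1:
            vhats[j] = out_beats[0]
            _phi_from_records(
                rec_path, rec_r, rec_d, n_rec, phis_prev[j], thetas[j], rts[j],
                out_beats[0], n_per_path, phis[j],
            )
        else:
            vhats[j] = np.nan
            for c in range(4):
                phis[j, c] = phis_prev[j, c]


@njit(cache=True)
def ecg_step_all(
    thetas_prev,   # (N, 12) parameters governing the interval before v_prev
    thetas_new,    # (N, 12) parameters after v_prev
    v_prev,        # (N,) stored previous simulated beat (nan on first step)
    rts, hts, hns, hos, hss, heap_sizes, seqs,  # (N, ...) state at the previous trigger
    alphas,        # (N, L) per-particle generated atrial series (anchored at a_prev)
    alpha_lens,    # (N,)
    n_per_path,
    cpl_r, cpl_d,
    horizon,
    tol,           # |V'_{k-1} - V_{k-1}| tolerance for the re-simulation check
    first_step,    # bool: single-beat mode without the re-simulation check
    phis_prev,     # (N, 4)
    rec_cap,
    vhats,         # (N,) out: new simulated beat (nan = excluded / no beat)
    a_new,         # (N,) out: atrial impulse leading to the new beat
    phis,          # (N, 4) out
):
    """Two-beat re-simulation step of the non-invasive (f-wave driven) filter.

    Pass 1 re-simulates from the state saved at the previous trigger
    impulse with ``thetas_prev`` before ``v_prev`` and ``thetas_new``
    after; particles whose re-simulated previous beat differs from the
    stored one are excluded (nan).  Pass 2 replays deterministically up to
    the new trigger impulse and leaves that snapshot in the state arrays.
    """
    n_particles = thetas_new.shape[0]
    heap_cap = hts.shape[1]
    rec_t = np.empty(rec_cap)
    rec_r = np.empty(rec_cap)
    rec_d = np.empty(rec_cap)
    rec_path = np.empty(rec_cap, dtype=np.int8)
    out_beats = np.empty(16)
    out_origins = np.empty(16)
    s_rt = np.empty(rts.shape[1])
    s_ht = np.empty(heap_cap)
    s_hn = np.empty(heap_cap, dtype=np.int64)
    s_ho = np.empty(heap_cap)
    s_hs = np.empty(heap_cap, dtype=np.int64)
    for j in range(n_particles):
        aa = alphas[j, : alpha_lens[j]]
        # scratch copy of the saved state for pass 1
        for i in range(rts.shape[1]):
            s_rt[i] = rts[j, i]
        for i in range(heap_sizes[j]):
            s_ht[i] = hts[j, i]
            s_hn[i] = hns[j, i]
            s_ho[i] = hos[j, i]
            s_hs[i] = hss[j, i]
        single = first_step or not np.isfinite(v_prev[j])
        if single:
            # first step, or a particle revived by the degenerate-ensemble
            # fallback without a stored previous beat: single-beat mode
            switch = -np.inf
            rec_from = -np.inf
        else:
            switch = v_prev[j]
            rec_from = v_prev[j]
        # replay beats one at a time: beats at or before the stored previous
        # beat are re-simulations of already-weighted history (in-flight
        # impulses, double responses); one of them must reproduce the stored
        # beat, and the first beat beyond it is the new simulated beat
        matched = single
        beat = np.nan
        trig = np.nan
        hsz = heap_sizes[j]
        seq = seqs[j]
        aptr = 0
        n_rec = 0
        for _attempt in range(16):
            status, hsz, seq, aptr, nr = run_engine(
                thetas_prev[j], thetas_new[j], switch,
                s_rt, s_ht, s_hn, s_ho, s_hs,
                hsz, seq, aa, aptr,
                n_per_path, cpl_r, cpl_d, horizon, 1,
                np.inf, rec_from,
                rec_t[n_rec:], rec_path[n_rec:], rec_r[n_rec:], rec_d[n_rec:],
                out_beats, out_origins,
            )
            if status != 1:
                break
            n_rec += nr
            b = out_beats[0]
            if (not single) and b <= v_prev[j] + tol:
                if np.abs(b - v_prev[j]) <= tol:
                    matched = True
                continue
            beat = b
            trig = out_origins[0]
            break
        ok = matched and np.isfinite(beat)
        if not ok:
            vhats[j] = np.nan
            a_new[j] = np.nan
            for c in range(4):
                phis[j, c] = phis_prev[j, c]
            continue
        vhats[j] = beat
        a_new[j] = trig
        _phi_from_records(
            rec_path, rec_r, rec_d, n_rec, phis_prev[j], thetas_new[j], s_rt,
            beat, n_per_path, phis[j],
        )
        # pass 2: replay up to the new trigger impulse, snapshot into state rows
        status2, hsz2, seq2, _aptr2, _nr2 = run_engine(
            thetas_prev[j], thetas_new[j], switch,
            rts[j], hts[j], hns[j], hos[j], hss[j],
            heap_sizes[j], seqs[j], aa, 0,
            n_per_path, cpl_r, cpl_d, np.inf, 16,
            trig, -np.inf,
            rec_t, rec_path, rec_r, rec_d,
            out_beats, out_origins,
        )
        heap_sizes[j] = hsz2
        seqs[j] = seq2
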