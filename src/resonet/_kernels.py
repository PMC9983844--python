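"""Numba kernels for synchronous threshold dynamics.

The update rule: node ``i`` at time ``t+1`` is 0 if the weighted sum of its
regulators' states at time ``t`` is negative, 1 if positive, and keeps its
previous value on an exact tie (which includes the no-regulator case, where
the sum is empty and exactly zero).  All nodes update in parallel.  A forced
hub overrides the rule:

* mode ``FREE``    -- the hub follows the rule like any other node;
* mode ``BLOCKED`` -- the hub is pinned to ``signal[0]``;
* mode ``DRIVEN``  -- the hub follows ``signal[t % len(signal)]``.

States are carried both as ``uint8`` vectors (logged, hashed, compared) and
as a ``float64`` shadow used in the weighted sums; the branch-free
multiply-accumulate is substantially faster than conditional adds because
its cost does not depend on the (unpredictable) node states.

Attractor detection stores the trajectory and finds the first recurrence with
an open-addressing hash table, either of the pair (state, t mod T) — which
guarantees a true cycle of the driven map — or of the bare state (the
time-independent notion, which under driving yields the first recurrence
segment rather than a certified cycle).
"""

import numpy as np
from numba import njit

FREE = 0
BLOCKED = 1
DRIVEN = 2

_FNV_OFFSET = np.uint64(0xCBF29CE484222325)
_FNV_PRIME = np.uint64(0x100000001B3)


@njit(cache=True, fastmath=True)
def _advance(indptr, src, w, state, statef, new, newf):
    """One synchronous update of every node (no forcing applied)."""
    for i in range(state.size):
        s = 0.0
        for e in range(indptr[i], indptr[i + 1]):
            s += w[e] * statef[src[e]]
        if s < 0.0:
            v = np.uint8(0)
        elif s > 0.0:
            v = np.uint8(1)
        else:
            v = state[i]
        new[i] = v
        newf[i] = v


@njit(cache=True)
def _state_hash(state):
    h = _FNV_OFFSET
    for i in range(state.size):
        h = (h ^ np.uint64(state[i])) * _FNV_PRIME
    return h


@njit(cache=True)
def _apply_forcing(state, statef, mode, signal, hub, t):
    if mode == BLOCKED:
        state[hub] = signal[0]
        statef[hub] = signal[0]
    elif mode == DRIVEN:
        v = signal[t % signal.size]
        state[hub] = v
        statef[hub] = v


@njit(cache=True)
def _find_recurrence(indptr, src, w, state0, mode, signal, hub, max_steps, match_phase):
    """Run from ``state0`` until the first recurrence.

    Returns ``(t1, length, log)`` where ``log[t]`` is the state at time ``t``
    (forcing applied, ``log[0]`` included), the recurrence pairs time ``t1``
    with time ``t1 + length``, and ``t1 == -1`` signals no recurrence within
    ``max_steps`` (``length`` then reports the steps actually taken).
    """
    n = state0.size
    period = signal.size if mode == DRIVEN else 1
    log = np.empty((max_steps + 1, n), np.uint8)
    hsize = 1
    while hsize < 2 * (max_steps + 2):
        hsize <<= 1
    mask = np.int64(hsize - 1)
    table = np.full(hsize, -1, np.int64)
    state = state0.copy()
    statef = state0.astype(np.float64)
    _apply_forcing(state, statef, mode, signal, hub, 0)
    log[0] = state
    slot = np.int64(_state_hash(state) & np.uint64(mask))
    table[slot] = 0
    new = np.empty(n, np.uint8)
    newf = np.empty(n, np.float64)
    for t in range(1, max_steps + 1):
        _advance(indptr, src, w, state, statef, new, newf)
        _apply_forcing(new, newf, mode, signal, hub, t)
        state[:] = new
        statef[:] = newf
        log[t] = state
        slot = np.int64(_state_hash(state) & np.uint64(mask))
        while True:
            idx = table[slot]
            if idx < 0:
                table[slot] = t
                break
            ok = True
            if match_phase and (t - idx) % period != 0:
                ok = False
            if ok:
                for i in range(n):
                    if log[idx, i] != state[i]:
                        ok = False
                        break
                if ok:
                    return idx, t - idx, log
            slot = (slot + 1) & mask
    return -1, max_steps, log


@njit(cache=True)
def _propagate(indptr, src, w, state, t0, n_steps, mode, signal, hub):
    """Advance ``state`` in place by ``n_steps`` updates starting at time ``t0``."""
    n = state.size
    statef = state.astype(np.float64)
    new = np.empty(n, np.uint8)
    newf = np.empty(n, np.float64)
    for s in range(n_steps):
        _advance(indptr, src, w, state, statef, new, newf)
        _apply_forcing(new, newf, mode, signal, hub, t0 + s + 1)
        state[:] = new
        statef[:] = newf


@njit(cache=True)
def _hamming_trace(indptr, src, w, sa, sb, n_steps, mode, signal, hub, out):
    """Co-evolve two states; record their normalized Hamming distance per step.

    ``out`` must have length ``n_steps + 1``; entry ``t`` is the distance at
    time ``t`` (both states get the forcing applied at t=0 first).
    """
    n = sa.size
    saf = sa.astype(np.float64)
    sbf = sb.astype(np.float64)
    _apply_forcing(sa, saf, mode, signal, hub, 0)
    _apply_forcing(sb, sbf, mode, signal, hub, 0)
    d = 0
    for i in range(n):
        if sa[i] != sb[i]:
            d += 1
    out[0] = d / n
    na = np.empty(n, np.uint8)
    nb = np.empty(n, np.uint8)
    naf = np.empty(n, np.float64)
    nbf = np.empty(n, np.float64)
    for s in range(n_steps):
        _advance(indptr, src, w, sa, saf, na, naf)
        _advance(indptr, src, w, sb, sbf, nb, nbf)
        _apply_forcing(na, naf, mode, signal, hub, s + 1)
        _apply_forcing(nb, nbf, mode, signal, hub, s + 1)
        sa[:] = na
        saf[:] = naf
        sb[:] = nb
        sbf[:] = nbf
        d = 0
        for i in range(n):
            if sa[i] != sb[i]:
                d += 1
        out[s + 1] = d / n
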