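"""Independent brute-force oracles for small networks.

Everything here is deliberately written against a *dense* weight matrix and
exhaustive enumeration of the full 2^N state space, sharing no code with the
package's sparse/incremental simulation path, so it can certify attractors,
transients and heights on small networks.
"""

import numpy as np


def dense_weights(net) -> np.ndarray:
    """W[i, j] = weight of edge j -> i (0 where absent)."""
    W = np.zeros((net.n_nodes, net.n_nodes))
    for (s, t), w in net.weights.items():
        W[t, s] = w
    return W


def all_states(n: int) -> np.ndarray:
    """(2^n, n) matrix of every state; state integer i has node j = bit j of i."""
    ints = np.arange(2 ** n)
    return ((ints[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int64)


def encode(states: np.ndarray) -> np.ndarray:
    n = states.shape[-1]
    return states @ (1 << np.arange(n))


def successor_tables(net, mode: str, signal=None, blocked_value=None):
    """One successor array per input phase.

    ``tables[p][s]`` is the integer successor of state ``s`` when the update
    happens at a time ``t`` with ``t % T == p`` (the new hub value is read at
    ``t + 1``).  For free/blocked dynamics there is a single phase.
    """
    n = net.n_nodes
    W = dense_weights(net)
    S = all_states(n)
    sums = S @ W.T
    base = np.where(sums < 0, 0, np.where(sums > 0, 1, S))
    if mode == "free":
        return [encode(base)]
    if mode == "blocked":
        nxt = base.copy()
        nxt[:, net.hub] = blocked_value
        return [encode(nxt)]
    T = len(signal)
    tables = []
    for p in range(T):
        nxt = base.copy()
        nxt[:, net.hub] = signal[(p + 1) % T]
        tables.append(encode(nxt))
    return tables


def force_initial(net, state_int: int, mode: str, signal=None, blocked_value=None) -> int:
    """Apply the t=0 forcing to an integer-coded state."""
    if mode == "free":
        return state_int
    v = blocked_value if mode == "blocked" else signal[0]
    if v:
        return state_int | (1 << net.hub)
    return state_int & ~(1 << net.hub)


def walk_to_cycle(tables, start_int: int, match_phase: bool = True):
    """Follow successors from (start, phase 0) until the first recurrence.

    Returns (transient, cycle) where cycle is the list of (state_int, phase)
    pairs starting at the first recurring element.  With ``match_phase=False``
    recurrence is on the bare state (the time-independent definition).
    """
    T = len(tables)
    seen = {}
    order = []
    s, p, t = start_int, 0, 0
    while True:
        key = (s, p) if match_phase else s
        if key in seen:
            t1 = seen[key]
            return t1, order[t1:]
        seen[key] = t
        order.append((s, p))
        s = tables[p][s]
        p = (p + 1) % T
        t += 1


def blocked_cycle_states(tables_blocked) -> set:
    """All integer states lying on a cycle of a single-phase successor table."""
    succ = tables_blocked[0]
    on_cycle = set()
    done = set()
    for start in range(succ.size):
        path = []
        pos = {}
        s = start
        while True:
            if s in done:
                break
            if s in pos:
                on_cycle.update(path[pos[s]:])
                break
            pos[s] = len(path)
            path.append(s)
            s = succ[s]
        done.update(path)
    return on_cycle


def height_of(tables_blocked, cycle_states: set, start_int: int) -> int:
    """Steps from ``start_int`` until the walk first sits on a blocked cycle."""
    succ = tables_blocked[0]
    s, h = start_int, 0
    while s not in cycle_states:
        s = succ[s]
        h += 1
    return h
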