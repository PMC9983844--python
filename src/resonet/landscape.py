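"""Attractor-landscape analysis under blocked and oscillating hubs.

The *ground-state* landscape of a network is the set of attractor cycles
reached when the hub is held constant at 0 or at 1 — the unperturbed
reference against which driven behaviour is measured.  The *height* of a
network state is the number of synchronous steps it needs, with the hub
blocked, to first land on a ground-state cycle; states on ground cycles have
height 0, and the mean height of a driven attractor measures how deep into
the reference basins the oscillation has pushed the network.  The
*relaxation time* is the mean number of steps needed to settle onto a new
ground cycle after the blocked hub value is flipped; twice the relaxation
time bounds the longest driving period that can still create new attractors.
The perturbation *order parameter* (asymptotic normalized Hamming distance
between trajectories from an initial state and a slightly perturbed copy)
locates the order-chaos transition of the network family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .dynamics import (
    Attractor,
    ForcingProtocol,
    NonConvergence,
    random_state,
    run_to_attractor,
)
from .errors import InvalidParameterError
from .network import ThresholdNetwork, build_network, sample_out_degrees
from .signals import BinarySignal, square_wave

__all__ = [
    "GroundStateLandscape",
    "ground_state_landscape",
    "state_height",
    "attractor_height",
    "relaxation_time",
    "attractor_novelty",
    "landscape_density",
    "landscape_graph",
    "perturbation_trace",
    "order_parameter",
    "transition_gamma",
]

DEFAULT_MAX_STEPS = 10_000


@dataclass
class GroundStateLandscape:
    """Distinct attractors found with the hub blocked at 0 and at 1."""

    attractors_off: list
    attractors_on: list
    n_init: int
    n_nonconverged: int = 0

    def attractors(self, blocked_value: int) -> list:
        return self.attractors_on if blocked_value else self.attractors_off

    def state_set(self, blocked_value=None) -> set:
        """Union of raw cycle states (bytes keys); both blockings if ``None``."""
        values = (0, 1) if blocked_value is None else (blocked_value,)
        out: set = set()
        for v in values:
            for a in self.attractors(v):
                out |= a.state_set()
        return out

    @property
    def n_attractors(self) -> int:
        return len(self.attractors_off) + len(self.attractors_on)


def _as_signal(period_or_signal) -> BinarySignal:
    if isinstance(period_or_signal, BinarySignal):
        return period_or_signal
    return square_wave(int(period_or_signal))


def ground_state_landscape(
    net: ThresholdNetwork,
    n_init: int,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> GroundStateLandscape:
    """Sample the blocked-hub attractor landscape from random initial states.

    The same ``n_init`` random initial conditions are relaxed once with the
    hub blocked at 0 and once blocked at 1; duplicate attractors are merged
    by canonical rotation.  Non-convergent trials are counted and excluded.
    """
    if n_init < 1:
        raise InvalidParameterError("n_init must be >= 1")
    inits = [random_state(net.n_nodes, rng) for _ in range(n_init)]
    found = {0: {}, 1: {}}
    n_bad = 0
    for b in (0, 1):
        forcing = ForcingProtocol.blocked(b)
        for s0 in inits:
            res = run_to_attractor(net, s0, forcing, max_steps=max_steps)
            if isinstance(res, NonConvergence):
                n_bad += 1
                continue
            found[b].setdefault(res.canonical_key(), res)
    return GroundStateLandscape(
        attractors_off=list(found[0].values()),
        attractors_on=list(found[1].values()),
        n_init=n_init,
        n_nonconverged=n_bad,
    )


def state_height(
    net: ThresholdNetwork,
    state,
    blocked_value: int,
    max_steps: int = DEFAULT_MAX_STEPS,
):
    """Steps under a blocked hub until the state first sits on a ground cycle.

    Equal to the transient length of the blocked relaxation from ``state``
    (the cycle the trajectory joins *is* a ground-state cycle of that
    blocking).  Returns ``None`` if the relaxation does not converge within
    ``max_steps``.  If the state's hub bit disagrees with ``blocked_value``
    the hub is pinned first, before the first counted step.
    """
    res = run_to_attractor(net, state, ForcingProtocol.blocked(blocked_value), max_steps=max_steps)
    if isinstance(res, NonConvergence):
        return None
    return int(res.transient_length)


def attractor_height(
    net: ThresholdNetwork,
    attractor: Attractor,
    mode: str = "stopped",
    max_steps: int = DEFAULT_MAX_STEPS,
):
    """Mean height of an attractor's cycle states.

    ``mode="stopped"`` (default) freezes the hub at each state's *own* hub
    bit — the oscillation simply stops — so a cycle that already lives on a
    ground cycle has height exactly 0.  ``mode="both"`` instead averages the
    blocked-at-0 and blocked-at-1 relaxations of every state, which charges
    even a ground-state cycle for the relaxation under the opposite blocking.
    Returns ``None`` if any required relaxation fails to converge.
    """
    if mode not in ("stopped", "both"):
        raise InvalidParameterError(f"unknown height mode {mode!r}")
    heights = []
    for j in range(attractor.period):
        s = attractor.states[j]
        if mode == "stopped":
            h = state_height(net, s, int(s[net.hub]), max_steps=max_steps)
            if h is None:
                return None
            heights.append(h)
        else:
            h0 = state_height(net, s, 0, max_steps=max_steps)
            h1 = state_height(net, s, 1, max_steps=max_steps)
            if h0 is None or h1 is None:
                return None
            heights.append(0.5 * (h0 + h1))
    return float(np.mean(heights))


def relaxation_time(
    net: ThresholdNetwork,
    rng: np.random.Generator,
    n_trials: int,
    max_steps: int = DEFAULT_MAX_STEPS,
):
    """Mean steps to reach a new ground cycle after flipping the blocked hub.

    Each trial: relax a random initial state with the hub blocked at ``b``,
    then flip the blocking to ``1 - b`` and count the steps (transient) until
    the trajectory joins a cycle of the new blocking.  Both flip directions
    are sampled equally (``b`` alternates).  Non-convergent trials are
    skipped; returns ``None`` if no trial converged.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    times = []
    for trial in range(n_trials):
        b = trial % 2
        first = run_to_attractor(
            net, random_state(net.n_nodes, rng), ForcingProtocol.blocked(b), max_steps=max_steps
        )
        if isinstance(first, NonConvergence):
            continue
        second = run_to_attractor(
            net, first.states[0], ForcingProtocol.blocked(1 - b), max_steps=max_steps
        )
        if isinstance(second, NonConvergence):
            continue
        times.append(second.transient_length)
    return float(np.mean(times)) if times else None


def attractor_novelty(resonant_states: set, ground_states: set) -> float:
    """``1 - |A_T ∩ B| / |A_T|`` over sets of raw network states.

    ``resonant_states`` is the state set of the driven landscape (``A_T``)
    and ``ground_states`` the blocked reference (``B``); 0 means the driven
    cycles reuse only ground states, 1 means they are entirely new.
    """
    if not resonant_states:
        raise InvalidParameterError("resonant state set is empty")
    shared = len(resonant_states & ground_states)
    return 1.0 - shared / len(resonant_states)


def landscape_density(
    net: ThresholdNetwork,
    period_or_signal,
    n_init: int,
    rng: np.random.Generator,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> float:
    """Fraction of random initial conditions that yield *distinct* driven attractors.

    Runs ``n_init`` random initial states under hub driving and counts
    distinct attractor cycles (canonical rotation of the (state, phase)
    cycle), divided by ``n_init``.  A small density means the driven
    landscape is robust: many initial conditions funnel into few cycles.
    """
    if n_init < 1:
        raise InvalidParameterError("n_init must be >= 1")
    forcing = ForcingProtocol.driven(_as_signal(period_or_signal))
    distinct = set()
    for _ in range(n_init):
        res = run_to_attractor(net, random_state(net.n_nodes, rng), forcing, max_steps=max_steps)
        if isinstance(res, NonConvergence):
            continue
        distinct.add(res.canonical_key())
    return len(distinct) / n_init


def landscape_graph(
    net: ThresholdNetwork,
    n_init: int,
    rng: np.random.Generator,
    forcing: ForcingProtocol,
    max_steps: int = DEFAULT_MAX_STEPS,
):
    """State-transition edge list sampled from random initial conditions.

    Walks each trajectory to its attractor and records every observed
    transition as an edge between state indices (states numbered in order of
    first appearance).  Returns ``(edges, states, on_cycle)`` where ``edges``
    is a DataFrame with columns ``source``/``target``, ``states`` maps index
    to the raw state bytes, and ``on_cycle`` flags indices that belong to an
    attractor cycle — the raw material for funnel-style landscape renderings.
    """
    import pandas as pd

    index: dict = {}
    states: list = []
    on_cycle: set = set()
    edges = set()

    def idx_of(key):
        if key not in index:
            index[key] = len(states)
            states.append(key)
        return index[key]

    from .dynamics import trajectory

    for _ in range(n_init):
        s0 = random_state(net.n_nodes, rng)
        res = run_to_attractor(net, s0, forcing, max_steps=max_steps)
        if isinstance(res, NonConvergence):
            continue
        walk = trajectory(net, s0, forcing, res.transient_length + res.period)
        ids = [idx_of(row.tobytes()) for row in walk]
        for j in range(len(ids) - 1):
            edges.add((ids[j], ids[j + 1]))
        # the walk's final state is the recurrence of the first cycle state,
        # so the closing edge is already among the consecutive pairs
        on_cycle.update(ids[res.transient_length:])
    df = pd.DataFrame(sorted(edges), columns=["source", "target"])
    return df, states, on_cycle


def perturbation_trace(
    net: ThresholdNetwork,
    state0,
    d: float,
    t_max: int,
    rng: np.random.Generator,
    forcing: ForcingProtocol = None,
) -> np.ndarray:
    """Hamming-distance time course between a trajectory and a perturbed copy.

    Flips ``ceil(d * N)`` distinct randomly chosen bits of ``state0`` (the
    hub is excluded from the flips whenever forcing pins it — a forced hub
    cannot hold a perturbation) and co-evolves both states for ``t_max``
    steps under identical forcing.  Returns the length ``t_max + 1`` trace of
    normalized Hamming distances.
    """
    if forcing is None:
        forcing = ForcingProtocol.free()
    if not (0.0 <= d <= 1.0):
        raise InvalidParameterError("perturbed fraction d must lie in [0, 1]")
    state0 = np.asarray(state0, dtype=np.uint8)
    n = net.n_nodes
    n_flip = int(np.ceil(d * n))
    candidates = np.arange(n)
    if forcing.mode != "free":
        candidates = candidates[candidates != net.hub]
    flip = rng.choice(candidates, size=min(n_flip, candidates.size), replace=False)
    sa = state0.copy()
    sb = state0.copy()
    sb[flip] ^= 1
    mode, sig = forcing._kernel_args()
    indptr, src, w = net.in_csr()
    out = np.empty(t_max + 1, np.float64)
    K._hamming_trace(indptr, src, w, sa, sb, t_max, mode, sig, net.hub, out)
    return out


def order_parameter(
    gamma: float,
    n_networks: int,
    n_init: int,
    d: float,
    t_max: int,
    rng: np.random.Generator,
    forcing: ForcingProtocol = None,
    n_nodes: int = 500,
) -> float:
    """Ensemble-averaged asymptotic perturbation Hamming distance ⟨h⟩.

    For ``n_networks`` fresh networks at exponent ``gamma`` and ``n_init``
    random initial states each, perturb a fraction ``d`` of node states,
    co-evolve for ``t_max`` steps and average the final normalized Hamming
    distance.  ⟨h⟩ ≈ 0 in the ordered phase; in the chaotic phase it
    saturates near 0.2 (not 0.5) because a large fraction of nodes freeze.
    """
    if n_networks < 1 or n_init < 1:
        raise InvalidParameterError("n_networks and n_init must be >= 1")
    finals = []
    for _ in range(n_networks):
        net = build_network(sample_out_degrees(n_nodes, gamma, rng), rng, gamma=gamma)
        for _ in range(n_init):
            trace = perturbation_trace(
                net, random_state(n_nodes, rng), d, t_max, rng, forcing=forcing
            )
            finals.append(trace[-1])
    return float(np.mean(finals))


def transition_gamma(
    gammas,
    h_values,
    threshold: float = 0.02,
    floor=None,
) -> float:
    """Locate the order-chaos transition on a ⟨h⟩-vs-γ curve.

    Returns the γ at which, coming from the ordered side, the curve first
    rises above ``floor + threshold`` (linearly interpolated between grid
    points).  Because the keep-on-tie update rule leaves a nonzero
    perturbation-memory floor even in the ordered phase, the crossing is
    referenced to the curve's ordered-side floor, estimated by default as the
    mean over the top quartile of the γ grid (at least 3 points).  For a
    curve that decays to zero on the ordered side this reduces to the plain
    absolute-threshold scan.  Raises if the curve never crosses.
    """
    order = np.argsort(gammas)
    g = np.asarray(gammas, dtype=float)[order]
    h = np.asarray(h_values, dtype=float)[order]
    if g.size < 3:
        raise InvalidParameterError("need at least 3 grid points")
    if floor is None:
        n_plateau = max(3, g.size // 4)
        floor = float(h[-n_plateau:].mean())
    level = floor + threshold
    # walk from the ordered (large-gamma) side toward small gamma
    for i in range(g.size - 1, 0, -1):
        if h[i] <= level < h[i - 1]:
            frac = (level - h[i]) / (h[i - 1] - h[i])
            return float(g[i] - frac * (g[i] - g[i - 1]))
    if h[0] > level:
        return float(g[0])
    raise InvalidParameterError("order-parameter curve never exceeds the threshold")
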