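"""Deterministic synchronous threshold dynamics and attractor detection.

Every node updates in parallel by the sign of the weighted sum of its
regulators' states, keeping its previous value on an exact tie.  The hub may
additionally be *blocked* (pinned to a constant) or *driven* (it follows a
binary signal ``I(t)``, ignoring its incoming edges while forcing is active);
its incoming edges are retained in the network — they matter when the hub is
left free.

Because the dynamics are deterministic on a finite state space, every
trajectory ends on a cycle.  Under periodic driving the dynamical map is a
function of the pair ``(state, t mod T)``, so by default recurrence is
detected on that augmented pair, which guarantees that the reported cycle is
a true cycle (its length is then a multiple of ``T``).  The alternative
``recurrence="state"`` stops at the first repeat of the bare network state —
the classical time-independent definition — which under driving returns the
first recurrence segment (e.g. the ground cycle the network loops on within
one half-period of a slow square wave).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .errors import InvalidParameterError, ShapeError
from .signals import BinarySignal

__all__ = [
    "ForcingProtocol",
    "Attractor",
    "NonConvergence",
    "random_state",
    "step",
    "run_to_attractor",
    "trajectory",
    "write_trajectory",
    "hamming_distance",
]

DEFAULT_MAX_STEPS = 10_000


@dataclass(frozen=True)
class ForcingProtocol:
    """How the hub evolves: ``free``, ``blocked`` at 0/1, or ``driven`` by a signal."""

    mode: str
    blocked_value: int | None = None
    signal: BinarySignal | None = None

    def __post_init__(self):
        if self.mode not in ("free", "blocked", "driven"):
            raise InvalidParameterError(f"unknown forcing mode {self.mode!r}")
        if self.mode == "blocked" and self.blocked_value not in (0, 1):
            raise InvalidParameterError("blocked forcing needs blocked_value in {0, 1}")
        if self.mode == "driven":
            if self.signal is None or self.signal.period < 1:
                raise InvalidParameterError("driven forcing needs a signal with period >= 1")

    @classmethod
    def free(cls) -> "ForcingProtocol":
        return cls("free")

    @classmethod
    def blocked(cls, value: int) -> "ForcingProtocol":
        return cls("blocked", blocked_value=value)

    @classmethod
    def driven(cls, signal: BinarySignal) -> "ForcingProtocol":
        return cls("driven", signal=signal)

    def _kernel_args(self):
        if self.mode == "free":
            return K.FREE, np.zeros(1, np.uint8)
        if self.mode == "blocked":
            return K.BLOCKED, np.array([self.blocked_value], np.uint8)
        return K.DRIVEN, np.asarray(self.signal.pattern, np.uint8)

    @property
    def effective_period(self) -> int:
        """Input phase period: the signal period under driving, else 1."""
        return self.signal.period if self.mode == "driven" else 1


@dataclass
class Attractor:
    """A detected recurrence: transient length plus the recurring state cycle.

    ``states[j]`` is the ``j``-th cycle state (``uint8`` vectors of length N)
    and ``phases[j]`` the input phase ``t mod T`` at which it occurs; the
    cycle starts at absolute time ``transient_length``.  With phase-matched
    detection the cycle is exact: one update from ``states[j]`` at phase
    ``phases[j]`` yields ``states[(j+1) % L]``.
    """

    transient_length: int
    states: np.ndarray
    phases: np.ndarray

    @property
    def period(self) -> int:
        return int(self.states.shape[0])

    @property
    def n_nodes(self) -> int:
        return int(self.states.shape[1])

    def node_sequence(self, node: int) -> np.ndarray:
        return self.states[:, node]

    def state_set(self) -> set:
        """Set of raw network states on the cycle, as bytes keys."""
        return {self.states[j].tobytes() for j in range(self.period)}

    def canonical_key(self) -> tuple:
        """Rotation-invariant identity of the cycle.

        The cycle is rotated so that its lexicographically smallest
        ``(state bytes, phase)`` pair leads; two attractors are the same orbit
        iff their canonical keys are equal.
        """
        items = [
            (self.states[j].tobytes(), int(self.phases[j])) for j in range(self.period)
        ]
        lead = min(items)
        best = None
        for j, it in enumerate(items):
            if it != lead:
                continue
            rot = tuple(items[j:] + items[:j])
            if best is None or rot < best:
                best = rot
        return best

    def to_json_dict(self) -> dict:
        return {
            "transient": int(self.transient_length),
            "period": self.period,
            "phases": [int(p) for p in self.phases],
            "cycle_states": ["".join(map(str, row.tolist())) for row in self.states],
        }


@dataclass
class NonConvergence:
    """No recurrence was found within the step budget (typed outcome, not an error)."""

    steps: int
    partial_length: int = field(default=0)

    def __bool__(self):  # allows `if not result:` style checks
        return False


def random_state(n_nodes: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random initial network state."""
    return rng.integers(0, 2, size=n_nodes, dtype=np.uint8)


def _check_state(net, state) -> np.ndarray:
    state = np.asarray(state, dtype=np.uint8)
    if state.ndim != 1 or state.size != net.n_nodes:
        raise ShapeError(f"state length {state.size} != n_nodes {net.n_nodes}")
    return state


def step(net, state, forcing: ForcingProtocol, t: int = 0) -> np.ndarray:
    """One synchronous update from time ``t`` to ``t + 1``.

    The returned state has the forcing applied at time ``t + 1`` (a driven hub
    reads ``signal[(t+1) % T]``); the input ``state`` is taken as given.
    """
    state = _check_state(net, state)
    if t < 0:
        raise InvalidParameterError("t must be >= 0")
    mode, sig = forcing._kernel_args()
    indptr, src, w = net.in_csr()
    new = np.empty(net.n_nodes, np.uint8)
    newf = np.empty(net.n_nodes, np.float64)
    K._advance(indptr, src, w, state, state.astype(np.float64), new, newf)
    K._apply_forcing(new, newf, mode, sig, net.hub, t + 1)
    return new


def run_to_attractor(
    net,
    state0,
    forcing: ForcingProtocol,
    max_steps: int = DEFAULT_MAX_STEPS,
    recurrence: str = "state_phase",
):
    """Iterate from ``state0`` until the first recurrence.

    For blocked or driven forcing the hub bit of ``state0`` is overwritten
    with the forcing value at ``t = 0`` before the first update.  Returns an
    :class:`Attractor` (transient length + trimmed cycle) or a
    :class:`NonConvergence` outcome if no recurrence shows up within
    ``max_steps`` updates.

    ``recurrence="state_phase"`` (default) matches the pair
    ``(state, t mod T)`` and guarantees a true cycle whose length is a
    multiple of the driving period.  ``recurrence="state"`` matches the bare
    state, the time-independent definition; aperiodic (white-noise) signals
    always use bare-state matching since they have no phase.
    """
    if max_steps < 1:
        raise InvalidParameterError("max_steps must be >= 1")
    if recurrence not in ("state_phase", "state"):
        raise InvalidParameterError(f"unknown recurrence mode {recurrence!r}")
    state0 = _check_state(net, state0)
    mode, sig = forcing._kernel_args()
    if forcing.mode == "driven" and forcing.signal.aperiodic:
        recurrence = "state"
    match_phase = recurrence == "state_phase"
    indptr, src, w = net.in_csr()
    t1, length, log = K._find_recurrence(
        indptr, src, w, state0, mode, sig, net.hub, max_steps, match_phase
    )
    if t1 < 0:
        return NonConvergence(steps=max_steps, partial_length=length)
    period_t = sig.size if mode == K.DRIVEN else 1
    phases = (t1 + np.arange(length)) % period_t
    return Attractor(
        transient_length=int(t1),
        states=log[t1:t1 + length].copy(),
        phases=phases,
    )


def trajectory(net, state0, forcing: ForcingProtocol, n_steps: int) -> np.ndarray:
    """States at times ``0 .. n_steps`` as an ``(n_steps + 1, N)`` uint8 array.

    The forcing is applied at every time including ``t = 0``.
    """
    if n_steps < 0:
        raise InvalidParameterError("n_steps must be >= 0")
    state = _check_state(net, state0).copy()
    mode, sig = forcing._kernel_args()
    statef = state.astype(np.float64)
    K._apply_forcing(state, statef, mode, sig, net.hub, 0)
    out = np.empty((n_steps + 1, net.n_nodes), np.uint8)
    out[0] = state
    indptr, src, w = net.in_csr()
    for t in range(n_steps):
        K._propagate(indptr, src, w, state, t, 1, mode, sig, net.hub)
        out[t + 1] = state
    return out


def write_trajectory(states, path) -> None:
    """Plain-text trajectory export: one line of 0/1 characters per timestep."""
    with open(path, "w") as fh:
        for row in np.asarray(states, dtype=np.uint8):
            fh.write("".join(map(str, row.tolist())) + "\n")


def hamming_distance(a, b) -> float:
    """Mean absolute difference between two equal-length binary sequences."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ShapeError("sequences must be 1-D, non-empty and of equal length")
    return float(np.mean(np.abs(a - b)))
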