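"""Binary hub-input signals and random binary target functions.

Three input classes drive the hub in the experiments: symmetric square waves
of even period ``T`` (``T/2`` ones then ``T/2`` zeros), repeated random
patterns of period ``T`` (a fixed random word tiled forever), and fixed
aperiodic "white-noise" sequences with no characteristic timescale.  Target
functions are fixed random binary words of length ``L_c`` that the output
node is evolved to reproduce.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "BinarySignal",
    "TargetFunction",
    "square_wave",
    "repeated_pattern",
    "white_noise",
    "random_target",
]


class BinarySignal:
    """A binary hub-input signal.

    ``pattern`` is the fundamental word; the hub follows
    ``pattern[t % period]`` with ``period == len(pattern)``.  Aperiodic
    (white-noise) signals carry ``aperiodic=True``: their pattern is a fixed
    sequence, not a fundamental period, and phase bookkeeping beyond its
    length is meaningless.
    """

    def __init__(self, pattern, aperiodic: bool = False):
        pattern = np.asarray(pattern, dtype=np.uint8)
        if pattern.ndim != 1 or pattern.size == 0:
            raise InvalidParameterError("signal pattern must be a non-empty 1-D sequence")
        if not np.all((pattern == 0) | (pattern == 1)):
            raise InvalidParameterError("signal pattern must be binary")
        self.pattern = pattern
        self.pattern.setflags(write=False)
        self.aperiodic = bool(aperiodic)

    @property
    def period(self) -> int:
        return int(self.pattern.size)

    def value_at(self, t: int) -> int:
        return int(self.pattern[t % self.pattern.size])

    def tile(self, n: int) -> np.ndarray:
        """First ``n`` values of the tiled signal."""
        reps = -(-n // self.pattern.size)
        return np.tile(self.pattern, reps)[:n]

    def __eq__(self, other):
        return (
            isinstance(other, BinarySignal)
            and self.aperiodic == other.aperiodic
            and np.array_equal(self.pattern, other.pattern)
        )

    def __repr__(self):
        bits = "".join(map(str, self.pattern.tolist()))
        tag = ", aperiodic" if self.aperiodic else ""
        return f"BinarySignal({bits!r}{tag})"

    def to_string(self) -> str:
        return "".join(map(str, self.pattern.tolist()))

    @classmethod
    def from_string(cls, s: str, aperiodic: bool = False) -> "BinarySignal":
        return cls([int(c) for c in s], aperiodic=aperiodic)


class TargetFunction:
    """A fixed random binary word the output node must learn to emit.

    Immutable for the whole evolutionary run.
    """

    def __init__(self, values):
        values = np.asarray(values, dtype=np.uint8)
        if values.ndim != 1 or values.size == 0:
            raise InvalidParameterError("target must be a non-empty 1-D sequence")
        if not np.all((values == 0) | (values == 1)):
            raise InvalidParameterError("target must be binary")
        self.values = values
        self.values.setflags(write=False)

    @property
    def length(self) -> int:
        return int(self.values.size)

    def __eq__(self, other):
        return isinstance(other, TargetFunction) and np.array_equal(self.values, other.values)

    def __repr__(self):
        return f"TargetFunction({''.join(map(str, self.values.tolist()))!r})"

    def to_string(self) -> str:
        return "".join(map(str, self.values.tolist()))

    @classmethod
    def from_string(cls, s: str) -> "TargetFunction":
        return cls([int(c) for c in s])


def square_wave(period: int) -> BinarySignal:
    """Symmetric square wave: ``period/2`` ones followed by ``period/2`` zeros.

    ``period`` must be even (an odd period cannot be symmetric) and >= 2.
    The fundamental frequency is ``1/period`` per timestep.
    """
    if period < 2 or period % 2 != 0:
        raise InvalidParameterError("square-wave period must be an even integer >= 2")
    half = period // 2
    return BinarySignal(np.concatenate([np.ones(half, np.uint8), np.zeros(half, np.uint8)]))


def repeated_pattern(period: int, rng: np.random.Generator) -> BinarySignal:
    """Random binary word of length ``period``, tiled forever.

    Constant words (all-0 / all-1) are rejected and redrawn: a constant
    "oscillation" is just a blocked hub.  ``period == 1`` therefore cannot
    produce a valid signal and is an error.
    """
    if period < 2:
        raise InvalidParameterError("repeated-pattern period must be >= 2 (a length-1 pattern is constant)")
    while True:
        bits = rng.integers(0, 2, size=period, dtype=np.uint8)
        if bits.min() != bits.max():
            return BinarySignal(bits)


def white_noise(length: int, rng: np.random.Generator) -> BinarySignal:
    """Fixed uniform random bit sequence with no characteristic timescale.

    The sequence is drawn once and reused identically wherever the signal is
    applied (it is a *fixed* aperiodic input, not fresh noise per use).
    """
    if length < 1:
        raise InvalidParameterError("white-noise length must be >= 1")
    return BinarySignal(rng.integers(0, 2, size=length, dtype=np.uint8), aperiodic=True)


def random_target(length: int, rng: np.random.Generator) -> TargetFunction:
    """Uniform random binary target function of length ``length``."""
    if length < 1:
        raise InvalidParameterError("target length must be >= 1")
    return TargetFunction(rng.integers(0, 2, size=length, dtype=np.uint8))
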