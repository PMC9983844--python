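"""Power spectra of node time series on attractors.

A node's behaviour on an attractor is a periodic binary sequence; tiling a
whole number of cycle repetitions and taking a raw (boxcar) periodogram
yields leakage-free spectral lines at multiples of ``1/L``.  Frequencies are
in per-timestep units, so the grid spans ``[0, 0.5]``.  When the hub is
driven at period ``T`` the input frequency is ``N0 = 1/T``; downstream nodes
respond at harmonics (and sometimes subharmonics) of ``N0``, which the
resonance map displays on an ``N0``-normalized frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .dynamics import Attractor, ForcingProtocol, NonConvergence, random_state, run_to_attractor
from .errors import InvalidParameterError, ResonetError
from .signals import BinarySignal

__all__ = ["NodeSpectrum", "node_power_spectrum", "is_frozen", "resonance_map"]


@dataclass
class NodeSpectrum:
    """One node's periodogram on an attractor.

    ``dominant_frequency`` maximizes power over the nonzero-frequency bins
    and is ``nan`` for a frozen node (no power anywhere above DC).
    """

    frequencies: np.ndarray
    power: np.ndarray
    dominant_frequency: float

    @property
    def is_frozen(self) -> bool:
        return bool(np.isnan(self.dominant_frequency))


def _tiled_sequence(attractor: Attractor, node: int, min_samples: int) -> np.ndarray:
    seq = attractor.node_sequence(node)
    reps = max(1, -(-min_samples // seq.size))
    return np.tile(seq, reps)


def node_power_spectrum(
    attractor: Attractor, node: int, min_samples: int = 512
) -> NodeSpectrum:
    """Raw periodogram of a node's cycle sequence tiled to ``>= min_samples``.

    The sequence is tiled by whole cycles (never truncated mid-cycle), so all
    power sits in exact spectral lines.  The mean is removed, and the
    zero-frequency bin is excluded when picking the dominant frequency.
    """
    if attractor.period < 1:
        raise InvalidParameterError("attractor period must be >= 1")
    x = _tiled_sequence(attractor, node, min_samples).astype(np.float64)
    freqs, power = periodogram(x, window="boxcar", detrend="constant", scaling="density")
    nz = power[1:]
    if x.var() == 0.0 or nz.max() <= 0.0:
        dominant = float("nan")
    else:
        dominant = float(freqs[1 + int(np.argmax(nz))])
    return NodeSpectrum(frequencies=freqs, power=power, dominant_frequency=dominant)


def is_frozen(attractor: Attractor, node: int) -> bool:
    """True iff the node's value is constant along the attractor cycle."""
    seq = attractor.node_sequence(node)
    return bool(seq.min() == seq.max())


def resonance_map(
    net,
    signal: BinarySignal,
    state0=None,
    rng: np.random.Generator = None,
    min_samples: int = 512,
    max_steps: int = 10_000,
) -> pd.DataFrame:
    """Per-node power spectra under hub driving, on a normalized frequency axis.

    Drives the hub with ``signal`` from ``state0`` (or a random state drawn
    from ``rng``), finds the attractor, and returns a DataFrame with one row
    per non-frozen node and one column per frequency bin, the frequency axis
    rescaled by the input frequency ``N0 = 1/T`` and each row normalized to
    unit maximum power.  The hub row sits at normalized frequency 1 by
    construction.
    """
    if state0 is None:
        if rng is None:
            raise InvalidParameterError("need either state0 or rng")
        state0 = random_state(net.n_nodes, rng)
    res = run_to_attractor(net, state0, ForcingProtocol.driven(signal), max_steps=max_steps)
    if isinstance(res, NonConvergence):
        raise ResonetError(f"no attractor within {max_steps} steps; cannot build resonance map")
    n0 = 1.0 / signal.period
    rows = {}
    freqs = None
    for node in range(net.n_nodes):
        if is_frozen(res, node):
            continue
        spec = node_power_spectrum(res, node, min_samples=min_samples)
        freqs = spec.frequencies / n0
        rows[node] = spec.power / spec.power.max()
    if not rows:
        raise ResonetError("every node is frozen on this attractor")
    return pd.DataFrame.from_dict(rows, orient="index", columns=freqs)
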