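"""Scale-free random Boolean threshold network construction and serialization.

Networks have ``N`` nodes and directed weighted edges.  The *out*-degree of
each node is drawn from the truncated power law ``P(k) = C k**-gamma`` on
``k in {1, ..., N-1}``; the targets of each node are chosen uniformly at
random from the other nodes, which makes the *in*-degree distribution
approximately Poisson (Erdos-Renyi-like).  Edge weights are uniform on
``[-1, 1]`` and strictly nonzero, so that ``w_ij == 0`` is synonymous with
"no edge".  The *hub* is the node of maximal out-degree (ties broken by the
lowest index); it is the node that external forcing acts on.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, UndefinedStatisticError

__all__ = [
    "ThresholdNetwork",
    "out_degree_pmf",
    "sample_out_degrees",
    "build_network",
    "asymmetry_parameter",
    "save_network",
    "load_network",
]


class ThresholdNetwork:
    """Weighted directed network with scale-free out-degree.

    Parameters
    ----------
    n_nodes
        Number of nodes ``N``; node indices are ``0 .. N-1``.
    src, tgt, weight
        Parallel edge arrays.  Edges need not be pre-sorted; they are stored
        sorted by source (stable within a source).
    gamma
        Scale-free exponent the out-degrees were drawn from (metadata; may be
        ``None`` for hand-built networks).
    hub
        Index of the forced node.  Defaults to the node of maximal out-degree,
        ties broken by the lowest index.
    """

    def __init__(self, n_nodes, src, tgt, weight, gamma=None, hub=None):
        if n_nodes < 1:
            raise InvalidParameterError("n_nodes must be >= 1")
        src = np.asarray(src, dtype=np.int64)
        tgt = np.asarray(tgt, dtype=np.int64)
        weight = np.asarray(weight, dtype=np.float64)
        if not (src.shape == tgt.shape == weight.shape):
            raise InvalidParameterError("src, tgt and weight must have equal length")
        if src.size:
            if src.min() < 0 or src.max() >= n_nodes or tgt.min() < 0 or tgt.max() >= n_nodes:
                raise InvalidParameterError("edge endpoint outside [0, n_nodes)")
            if np.any(src == tgt):
                raise InvalidParameterError("self-edges are not allowed")
            if np.any(weight == 0.0) or np.any(np.abs(weight) > 1.0):
                raise InvalidParameterError("weights must be nonzero and lie in [-1, 1]")
        order = np.argsort(src, kind="stable")
        self.n_nodes = int(n_nodes)
        self.src = np.ascontiguousarray(src[order])
        self.tgt = np.ascontiguousarray(tgt[order])
        self.weight = np.ascontiguousarray(weight[order])
        pairs = set(zip(self.src.tolist(), self.tgt.tolist()))
        if len(pairs) != self.src.size:
            raise InvalidParameterError("duplicate directed edges are not allowed")
        counts = np.bincount(self.src, minlength=n_nodes)
        self.out_indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        self.gamma = None if gamma is None else float(gamma)
        self.hub = int(np.argmax(counts)) if hub is None else int(hub)
        self._in_csr = None

    # -- basic queries ----------------------------------------------------

    @property
    def n_edges(self) -> int:
        return int(self.src.size)

    @property
    def out_degrees(self) -> np.ndarray:
        return np.diff(self.out_indptr)

    @property
    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.tgt, minlength=self.n_nodes)

    def targets_of(self, node: int) -> np.ndarray:
        lo, hi = self.out_indptr[node], self.out_indptr[node + 1]
        return self.tgt[lo:hi]

    def weights_of(self, node: int) -> np.ndarray:
        lo, hi = self.out_indptr[node], self.out_indptr[node + 1]
        return self.weight[lo:hi]

    @property
    def edges(self) -> set:
        """Edge set as ``{(source, target), ...}``."""
        return set(zip(self.src.tolist(), self.tgt.tolist()))

    @property
    def weights(self) -> dict:
        """Mapping ``(source, target) -> weight``."""
        return {
            (int(s), int(t)): float(w)
            for s, t, w in zip(self.src, self.tgt, self.weight)
        }

    def in_csr(self):
        """Incoming-edge CSR view ``(indptr, src, weight)`` used by the kernels.

        Row ``i`` lists the regulators of node ``i``.  Cached; network objects
        are treated as immutable (mutation returns a new network).
        """
        if self._in_csr is None:
            order = np.argsort(self.tgt, kind="stable")
            counts = np.bincount(self.tgt, minlength=self.n_nodes)
            indptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
            self._in_csr = (
                indptr,
                np.ascontiguousarray(self.src[order].astype(np.int32)),
                np.ascontiguousarray(self.weight[order]),
            )
        return self._in_csr

    def copy(self) -> "ThresholdNetwork":
        return ThresholdNetwork(
            self.n_nodes, self.src.copy(), self.tgt.copy(), self.weight.copy(),
            gamma=self.gamma, hub=self.hub,
        )

    def to_networkx(self):
        """Export as a ``networkx.DiGraph`` with ``weight`` edge attributes."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(zip(self.src.tolist(), self.tgt.tolist(), self.weight.tolist()))
        return g

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"ThresholdNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges}, "
            f"gamma={self.gamma}, hub={self.hub})"
        )


def out_degree_pmf(n_nodes: int, gamma: float) -> np.ndarray:
    """Normalized power-law pmf ``P(k) = C k**-gamma`` on ``k = 1 .. N-1``.

    Returns an array of length ``N-1``; entry ``j`` is ``P(k = j+1)``.
    """
    if n_nodes < 2:
        raise InvalidParameterError("n_nodes must be >= 2")
    if gamma <= 1.0:
        raise InvalidParameterError("gamma must be > 1")
    k = np.arange(1, n_nodes, dtype=np.float64)
    p = k ** (-float(gamma))
    return p / p.sum()


def sample_out_degrees(n_nodes: int, gamma: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``N`` i.i.d. out-degrees from ``P(k) = C k**-gamma``, ``k in 1..N-1``.

    Uses inverse-CDF sampling on the exact truncated pmf.
    """
    pmf = out_degree_pmf(n_nodes, gamma)
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0  # guard against rounding
    u = rng.random(n_nodes)
    return (np.searchsorted(cdf, u, side="right") + 1).astype(np.int64)


def build_network(
    degrees,
    rng: np.random.Generator,
    gamma: float | None = None,
    weight_interval: tuple = (-1.0, 1.0),
) -> ThresholdNetwork:
    """Wire a network from an out-degree sequence.

    Each node ``i`` gets ``k_i`` distinct targets sampled uniformly without
    replacement from the other ``N-1`` nodes; each edge receives an independent
    weight uniform on ``weight_interval`` with exact zeros redrawn (so that a
    zero weight always means "no edge").  The hub is the node of maximal
    out-degree, ties broken by the lowest index.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    n = degrees.size
    if n < 2:
        raise InvalidParameterError("need at least 2 nodes")
    if degrees.min() < 0 or degrees.max() > n - 1:
        raise InvalidParameterError("out-degree must lie in [0, N-1]")
    lo, hi = float(weight_interval[0]), float(weight_interval[1])
    if not (-1.0 <= lo < hi <= 1.0):
        raise InvalidParameterError("weight_interval must be a subinterval of [-1, 1]")
    src = np.repeat(np.arange(n), degrees)
    tgt = np.empty(src.size, dtype=np.int64)
    pos = 0
    for i in range(n):
        k = degrees[i]
        if k == 0:
            continue
        choice = rng.choice(n - 1, size=k, replace=False)
        choice[choice >= i] += 1  # skip the self index
        tgt[pos:pos + k] = choice
        pos += k
    w = rng.uniform(lo, hi, size=src.size)
    while np.any(w == 0.0):
        zeros = w == 0.0
        w[zeros] = rng.uniform(lo, hi, size=int(zeros.sum()))
    return ThresholdNetwork(n, src, tgt, w, gamma=gamma)


def asymmetry_parameter(net: ThresholdNetwork) -> float:
    """Weight-distribution asymmetry ``alpha_w = mean(w) / std(w)``.

    ``alpha_w = 0`` corresponds to balanced activation/inhibition; all
    experiments in this package use symmetric ``[-1, 1]`` weights.
    """
    if net.n_edges < 1:
        raise InvalidParameterError("network has no edges")
    std = float(np.std(net.weight))
    if std == 0.0:
        raise UndefinedStatisticError("weight standard deviation is zero")
    return float(np.mean(net.weight)) / std


def save_network(net: ThresholdNetwork, path, seed=None) -> None:
    """Write a network as a TSV edge list plus a JSON sidecar.

    The TSV has a header and one ``source<TAB>target<TAB>weight`` row per edge
    (weights at full ``repr`` precision); the sidecar ``<path>.json`` records
    ``{n_nodes, gamma, hub, seed}``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for s, t, w in zip(net.src, net.tgt, net.weight):
            fh.write(f"{int(s)}\t{int(t)}\t{float(w)!r}\n")
    meta = {"n_nodes": net.n_nodes, "gamma": net.gamma, "hub": net.hub, "seed": seed}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")


def load_network(path) -> ThresholdNetwork:
    """Read a network written by :func:`save_network` (exact round trip)."""
    path = Path(path)
    src, tgt, w = [], [], []
    with open(path) as fh:
        header = fh.readline()
        if header.split() != ["source", "target", "weight"]:
            raise InvalidParameterError(f"unrecognized network file header: {header!r}")
        for line in fh:
            if not line.strip():
                continue
            a, b, c = line.split("\t")
            src.append(int(a))
            tgt.append(int(b))
            w.append(float(c))
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    return ThresholdNetwork(
        meta["n_nodes"], src, tgt, w, gamma=meta.get("gamma"), hub=meta.get("hub")
    )
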