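"""Resonant-learning evolutionary algorithm.

A population of threshold networks is evolved so that one designated output
node reproduces predefined random binary target functions.  In the resonant
scheme each target ``f_i`` (length ``L_i``) is paired with a periodic hub
input of period ``T_i`` (conventionally ``L_i = T_i``): to score one pair
the network is run from a fresh random initial state with the hub driven by
the input until it reaches an attractor, and the output node's cycle
sequence is compared to the target by a circular-shift-minimized normalized
Hamming distance ``h``.  The aggregate fitness over ``M`` pairs is
``1 - mean_i(h_i^2)``.  Each generation every one of the ``N_pop`` parents
spawns ``M_mut`` mutants (a mutated node rewires or reweights one outgoing
edge, preserving the out-degree sequence exactly), all ``(1 + M_mut) *
N_pop`` candidates are scored, and the best ``N_pop`` survive.

Two control schemes replace the period-coded inputs: the hub is *blocked* at
a constant or left *free* to follow the update rule, and the ``M`` cases are
distinguished by ``M`` fixed predefined initial conditions instead of ``M``
driving signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import ForcingProtocol, NonConvergence, random_state, run_to_attractor
from .errors import InvalidParameterError
from .network import ThresholdNetwork
from .signals import BinarySignal, TargetFunction

__all__ = [
    "EvolutionConfig",
    "TargetSet",
    "FitnessRecord",
    "EvolutionResult",
    "score_single",
    "score_multiplex",
    "mutate",
    "evolve",
    "control_scheme_run",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the evolutionary loop.

    Defaults follow the headline experiments: population ``N_pop = 50``,
    3 mutants per parent, per-node mutation probability ``mu = 0.02``.
    ``scoring_scheme`` selects resonant driving (``"driven"``) or one of the
    fixed-hub controls (``"blocked"`` / ``"free"``).
    """

    pop_size: int = 50
    mutants_per_parent: int = 3
    mutation_rate: float = 0.02
    generations: int = 100
    max_steps: int = 10_000
    scoring_scheme: str = "driven"
    blocked_value: int = 1
    comparison: str = "lcm"
    fixed_scoring_ics: bool = False
    checkpoint_interval: int | None = None
    checkpoint_dir: str | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.pop_size < 1:
            raise InvalidParameterError("pop_size must be >= 1")
        if self.mutants_per_parent < 0:
            raise InvalidParameterError("mutants_per_parent must be >= 0")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise InvalidParameterError("mutation_rate must lie in [0, 1]")
        if self.generations < 0:
            raise InvalidParameterError("generations must be >= 0")
        if self.scoring_scheme not in ("driven", "blocked", "free"):
            raise InvalidParameterError(f"unknown scoring scheme {self.scoring_scheme!r}")
        if self.blocked_value not in (0, 1):
            raise InvalidParameterError("blocked_value must be 0 or 1")
        if self.comparison not in ("truncate", "lcm"):
            raise InvalidParameterError(f"unknown comparison mode {self.comparison!r}")
        if self.checkpoint_interval is not None and self.checkpoint_interval < 1:
            raise InvalidParameterError("checkpoint_interval must be >= 1")


@dataclass(frozen=True)
class TargetSet:
    """``M`` (input signal, target function) pairs plus the fixed output node.

    Both the output node and the targets stay fixed for the whole run.  In
    the default resonant convention each target's length equals its input's
    period.
    """

    pairs: tuple
    output_node: int
    hub: int | None = None

    def __post_init__(self):
        if not self.pairs:
            raise InvalidParameterError("target set must contain at least one pair")
        for sig, tf in self.pairs:
            if not isinstance(sig, BinarySignal) or not isinstance(tf, TargetFunction):
                raise InvalidParameterError("pairs must be (BinarySignal, TargetFunction)")
        if self.hub is not None and self.output_node == self.hub:
            raise InvalidParameterError("output node must differ from the hub")

    @property
    def n_targets(self) -> int:
        return len(self.pairs)


@dataclass
class FitnessRecord:
    """Per-target errors ``h_i`` and the aggregate fitness ``1 - mean(h_i^2)``."""

    errors: np.ndarray
    generation: int = -1

    @property
    def fitness(self) -> float:
        return 1.0 - float(np.mean(np.square(self.errors)))

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.errors))


def _shift_min_distance(out_seq: np.ndarray, target: np.ndarray, comparison: str) -> float:
    """Min over circular target rotations of the normalized Hamming distance.

    Both sequences are tiled to the comparison length: ``lcm(L, L_c)``
    (default, compares the full periodic extensions) or the lossy
    ``min(L, L_c)`` truncation for ``"truncate"``.  The truncating variant
    degenerates for fixed-point attractors (a length-1 cycle matches any
    target containing its bit), which is why it is not the default.
    """
    L, Lc = out_seq.size, target.size
    m = min(L, Lc) if comparison == "truncate" else int(np.lcm(L, Lc))
    a = np.resize(out_seq, m).astype(np.int16)
    # all circular permutations of the *full* target, each tiled/truncated to
    # the comparison length, so the score is exactly rotation-invariant
    doubled = np.concatenate([target, target[:-1]]) if Lc > 1 else target
    rolls = np.lib.stride_tricks.sliding_window_view(doubled, Lc).astype(np.int16)
    tiled = rolls[:, np.arange(m) % Lc]
    dists = np.abs(a[None, :] - tiled).mean(axis=1)
    return float(dists.min())


def score_single(
    net: ThresholdNetwork,
    signal: BinarySignal,
    target: TargetFunction,
    output_node: int,
    rng: np.random.Generator = None,
    max_steps: int = 10_000,
    comparison: str = "lcm",
    state0=None,
    forcing: ForcingProtocol = None,
) -> float:
    """Error ``h`` of one (input, target) pair for one network.

    Runs from a random initial state (or ``state0``) with the hub driven by
    ``signal`` (or under an explicit ``forcing`` for the control schemes),
    extracts the output node's attractor-cycle sequence, and returns the
    circular-shift-minimized normalized Hamming distance to the target.
    Non-convergent dynamics score the worst possible ``h = 1``.
    """
    if output_node == net.hub and (forcing is None or forcing.mode != "free"):
        raise InvalidParameterError("output node must differ from the (forced) hub")
    if state0 is None:
        if rng is None:
            raise InvalidParameterError("need either state0 or rng")
        state0 = random_state(net.n_nodes, rng)
    if forcing is None:
        forcing = ForcingProtocol.driven(signal)
    res = run_to_attractor(net, state0, forcing, max_steps=max_steps)
    if isinstance(res, NonConvergence):
        return 1.0
    return _shift_min_distance(res.node_sequence(output_node), target.values, comparison)


def score_multiplex(
    net: ThresholdNetwork,
    targets: TargetSet,
    rng: np.random.Generator = None,
    config: EvolutionConfig = None,
    initial_conditions=None,
    generation: int = -1,
) -> FitnessRecord:
    """Score all target pairs; aggregate fitness is ``1 - mean(h_i^2)``.

    In the driven scheme each pair gets a fresh random initial state and its
    own driving signal; in the blocked/free control schemes the pairs are
    distinguished by ``initial_conditions`` (one predefined state per pair)
    and the signals are ignored.
    """
    config = config or EvolutionConfig()
    errors = np.empty(targets.n_targets)
    for i, (sig, tf) in enumerate(targets.pairs):
        if config.scoring_scheme == "driven":
            errors[i] = score_single(
                net, sig, tf, targets.output_node, rng=rng,
                max_steps=config.max_steps, comparison=config.comparison,
            )
        else:
            if initial_conditions is None or len(initial_conditions) != targets.n_targets:
                raise InvalidParameterError(
                    "control schemes need one predefined initial condition per target"
                )
            forcing = (
                ForcingProtocol.blocked(config.blocked_value)
                if config.scoring_scheme == "blocked"
                else ForcingProtocol.free()
            )
            errors[i] = score_single(
                net, sig, tf, targets.output_node,
                max_steps=config.max_steps, comparison=config.comparison,
                state0=initial_conditions[i], forcing=forcing,
            )
    return FitnessRecord(errors=errors, generation=generation)


def mutate(net: ThresholdNetwork, mu: float, rng: np.random.Generator) -> ThresholdNetwork:
    """Mutate each node independently with probability ``mu``.

    A mutated node picks one of its outgoing edges uniformly; with
    probability 1/2 the edge weight is redrawn uniform on [-1, 1] (exact
    zeros redrawn), otherwise the edge is redirected to a uniformly chosen
    new target (never a self-edge, never a duplicate).  A node whose
    out-neighbourhood is already saturated falls back to a weight change.
    The out-degree sequence is exactly preserved.
    """
    if not (0.0 <= mu <= 1.0):
        raise InvalidParameterError("mu must lie in [0, 1]")
    n = net.n_nodes
    hit = rng.random(n) < mu
    if not hit.any():
        return ThresholdNetwork(
            n, net.src, net.tgt.copy(), net.weight.copy(), gamma=net.gamma, hub=net.hub
        )
    tgt = net.tgt.copy()
    weight = net.weight.copy()
    for node in np.flatnonzero(hit):
        lo, hi = net.out_indptr[node], net.out_indptr[node + 1]
        k = hi - lo
        if k == 0:
            continue
        e = lo + rng.integers(k)
        rewire = rng.random() < 0.5
        if rewire:
            taken = np.zeros(n, dtype=bool)
            taken[node] = True
            taken[tgt[lo:hi]] = True
            candidates = np.flatnonzero(~taken)
            if candidates.size:
                tgt[e] = candidates[rng.integers(candidates.size)]
                continue
            # saturated out-neighbourhood: fall through to a weight change
        wnew = rng.uniform(-1.0, 1.0)
        while wnew == 0.0:
            wnew = rng.uniform(-1.0, 1.0)
        weight[e] = wnew
    return ThresholdNetwork(n, net.src, tgt, weight, gamma=net.gamma, hub=net.hub)


@dataclass
class EvolutionResult:
    """Outcome of an evolutionary run.

    ``history`` is a tidy per-generation DataFrame (best/mean fitness and the
    best network's per-target errors); ``population`` is the final sorted
    population (best first).
    """

    history: pd.DataFrame
    population: list
    targets: TargetSet
    config: EvolutionConfig
    initial_conditions: list | None = None

    @property
    def best_network(self) -> ThresholdNetwork:
        return self.population[0]

    @property
    def best_fitness(self) -> float:
        return float(self.history["best_fitness"].iloc[-1]) if len(self.history) else float("nan")

    @property
    def best_error(self) -> float:
        return 1.0 - self.best_fitness

    def summary(self) -> str:
        lines = [
            "Resonant-learning evolutionary run",
            "==================================",
            f"scheme:            {self.config.scoring_scheme}",
            f"population size:   {self.config.pop_size} (+{self.config.mutants_per_parent} mutants/parent)",
            f"mutation rate:     {self.config.mutation_rate}",
            f"generations:       {len(self.history)}",
            f"targets:           {self.targets.n_targets} "
            f"(lengths {[tf.length for _, tf in self.targets.pairs]})",
            f"output node:       {self.targets.output_node}",
            f"final best fitness: {self.best_fitness:.4f} (error {self.best_error:.4f})",
        ]
        if len(self.history):
            hcols = [c for c in self.history.columns if c.startswith("h_")]
            final = self.history.iloc[-1]
            lines.append(
                "final per-target h: "
                + ", ".join(f"{c}={final[c]:.3f}" for c in hcols)
            )
        return "\n".join(lines)


def _write_checkpoint(population, config: EvolutionConfig, gen: int) -> None:
    from pathlib import Path

    from .network import save_network

    out = Path(config.checkpoint_dir) / f"generation_{gen:06d}"
    out.mkdir(parents=True, exist_ok=True)
    for i, net in enumerate(population):
        save_network(net, out / f"member_{i:03d}.tsv", seed=config.seed)


def _validate_population(population, targets):
    if not population:
        raise InvalidParameterError("population must be non-empty")
    for net in population:
        if targets.output_node == net.hub:
            raise InvalidParameterError("output node coincides with a population member's hub")
        if not (0 <= targets.output_node < net.n_nodes):
            raise InvalidParameterError("output node index out of range")


def evolve(
    population,
    targets: TargetSet,
    config: EvolutionConfig,
    rng: np.random.Generator,
    initial_conditions=None,
) -> EvolutionResult:
    """Run the mutation/selection loop for ``config.generations`` generations.

    Every generation all parents and their mutants are (re)scored — fresh
    random initial conditions per network and target in the driven scheme,
    the predefined ``initial_conditions`` in the control schemes (generated
    once from ``rng`` if not supplied) — and the top ``pop_size`` by
    aggregate fitness survive.  Ties are broken deterministically: parents
    before mutants, then lower index.  Because parents are rescored rather
    than carried with stale scores, the best fitness is monotone only when
    scoring is deterministic (``fixed_scoring_ics``).
    """
    _validate_population(population, targets)
    population = list(population)[: config.pop_size]
    n_nodes = population[0].n_nodes
    if config.scoring_scheme != "driven" and initial_conditions is None:
        initial_conditions = [random_state(n_nodes, rng) for _ in range(targets.n_targets)]
    fixed_ics = None
    if config.fixed_scoring_ics and config.scoring_scheme == "driven":
        fixed_ics = [random_state(n_nodes, rng) for _ in range(targets.n_targets)]
    rows = []
    for gen in range(config.generations):
        candidates = list(population)
        for parent in population:
            for _ in range(config.mutants_per_parent):
                candidates.append(mutate(parent, config.mutation_rate, rng))
        records = []
        for net in candidates:
            if fixed_ics is not None:
                errors = np.array([
                    score_single(
                        net, sig, tf, targets.output_node, state0=fixed_ics[i],
                        max_steps=config.max_steps, comparison=config.comparison,
                    )
                    for i, (sig, tf) in enumerate(targets.pairs)
                ])
                records.append(FitnessRecord(errors=errors, generation=gen))
            else:
                records.append(
                    score_multiplex(
                        net, targets, rng=rng, config=config,
                        initial_conditions=initial_conditions, generation=gen,
                    )
                )
        fitness = np.array([r.fitness for r in records])
        order = np.argsort(-fitness, kind="stable")
        keep = order[: config.pop_size]
        population = [candidates[i] for i in keep]
        best = records[keep[0]]
        row = {
            "generation": gen,
            "best_fitness": fitness[keep[0]],
            "mean_fitness": float(fitness[keep].mean()),
            "best_error": 1.0 - fitness[keep[0]],
        }
        for i, h in enumerate(best.errors):
            row[f"h_{i}"] = float(h)
        rows.append(row)
        if (
            config.checkpoint_interval is not None
            and config.checkpoint_dir is not None
            and (gen + 1) % config.checkpoint_interval == 0
        ):
            _write_checkpoint(population, config, gen)
    history = pd.DataFrame(rows)
    return EvolutionResult(
        history=history,
        population=population,
        targets=targets,
        config=config,
        initial_conditions=initial_conditions,
    )


def control_scheme_run(
    population,
    targets: TargetSet,
    config: EvolutionConfig,
    rng: np.random.Generator,
    initial_conditions=None,
) -> EvolutionResult:
    """Run the blocked- or free-hub control: targets keyed by fixed initial states.

    Identical loop to :func:`evolve`, but per-target differentiation comes
    from ``M`` predefined initial conditions instead of ``M`` driving
    signals; the hub is blocked at ``config.blocked_value`` or left free.
    """
    if config.scoring_scheme not in ("blocked", "free"):
        raise InvalidParameterError("control_scheme_run needs scoring_scheme 'blocked' or 'free'")
    return evolve(population, targets, config, rng, initial_conditions=initial_conditions)
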