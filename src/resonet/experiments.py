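"""Canned experiment protocols at the study's ensemble scales.

Each function wires together network generation, dynamics and analysis for
one of the headline measurements — relaxation times, the perturbation phase
diagram, driven-landscape density, long-period heights, and the
resonant-vs-control learning comparison — with every source of randomness
drawn from named child streams of a single master seed.  The default
ensemble sizes are single-CPU scaled-down versions of the originals (the
exact sizes used are documented in the methods note); the protocol
parameters (N, γ, d, t_max, periods, mutation rate, ...) are the study
conditions themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import child_rngs
from .dynamics import ForcingProtocol, NonConvergence, random_state, run_to_attractor
from .evolution import EvolutionConfig, TargetSet, control_scheme_run, evolve
from .landscape import (
    attractor_height,
    landscape_density,
    order_parameter,
    relaxation_time,
    transition_gamma,
)
from .network import build_network, sample_out_degrees
from .signals import random_target, repeated_pattern, square_wave, white_noise

__all__ = [
    "relaxation_time_ensemble",
    "chaotic_order_parameter",
    "order_parameter_curves",
    "transition_locations",
    "mean_landscape_density",
    "long_period_heights",
    "learning_run",
    "learning_comparison",
]


def _networks(rng, n_networks, n_nodes, gamma):
    return [
        build_network(sample_out_degrees(n_nodes, gamma, rng), rng, gamma=gamma)
        for _ in range(n_networks)
    ]


def relaxation_time_ensemble(
    seed: int,
    gamma: float,
    n_networks: int = 10,
    trials_per_network: int = 10,
    n_nodes: int = 1000,
    max_steps: int = 10_000,
) -> float:
    """Ensemble-mean relaxation time after flipping the blocked hub value."""
    rngs = child_rngs(seed, "topology", "trials")
    times = []
    for net in _networks(rngs["topology"], n_networks, n_nodes, gamma):
        t = relaxation_time(net, rngs["trials"], trials_per_network, max_steps=max_steps)
        if t is not None:
            times.append(t)
    return float(np.mean(times))


def chaotic_order_parameter(
    seed: int,
    gamma: float = 1.3,
    n_networks: int = 12,
    n_ics: int = 5,
    n_nodes: int = 500,
    d: float = 0.05,
    t_max: int = 300,
) -> float:
    """Asymptotic perturbation Hamming distance on the chaotic plateau.

    Under the keep-on-tie update rule the chaotic plateau of the ensemble
    sits at γ ≲ 1.4; the expected plateau value is ≈ 0.2 (not 0.5) because a
    large fraction of nodes stay frozen.
    """
    rngs = child_rngs(seed, "ensemble")
    return order_parameter(
        gamma, n_networks, n_ics, d, t_max, rngs["ensemble"],
        forcing=ForcingProtocol.free(), n_nodes=n_nodes,
    )


def order_parameter_curves(
    seed: int,
    gammas=None,
    n_networks: int = 16,
    n_ics: int = 5,
    n_nodes: int = 500,
    d: float = 0.05,
    t_max: int = 300,
    driving_period: int = 10,
) -> pd.DataFrame:
    """⟨h⟩ versus γ with the hub free and square-wave driven."""
    if gammas is None:
        gammas = np.round(np.arange(1.5, 3.01, 0.1), 10)
    rngs = child_rngs(seed, "free", "driven")
    rows = []
    for g in gammas:
        h_free = order_parameter(
            float(g), n_networks, n_ics, d, t_max, rngs["free"],
            forcing=ForcingProtocol.free(), n_nodes=n_nodes,
        )
        h_driven = order_parameter(
            float(g), n_networks, n_ics, d, t_max, rngs["driven"],
            forcing=ForcingProtocol.driven(square_wave(driving_period)), n_nodes=n_nodes,
        )
        rows.append({"gamma": float(g), "h_free": h_free, "h_driven": h_driven})
    return pd.DataFrame(rows)


def transition_locations(curves: pd.DataFrame, threshold: float = 0.02) -> dict:
    """Crossing γ of both order-parameter curves (floor-referenced threshold)."""
    return {
        "free": transition_gamma(curves["gamma"], curves["h_free"], threshold=threshold),
        "driven": transition_gamma(curves["gamma"], curves["h_driven"], threshold=threshold),
    }


def mean_landscape_density(
    seed: int,
    gamma: float = 1.9,
    n_networks: int = 10,
    n_init: int = 300,
    n_nodes: int = 1000,
    period: int = 4,
    max_steps: int = 10_000,
) -> float:
    """Mean fraction of initial conditions yielding distinct driven attractors."""
    rngs = child_rngs(seed, "topology", "ics")
    densities = [
        landscape_density(net, period, n_init, rngs["ics"], max_steps=max_steps)
        for net in _networks(rngs["topology"], n_networks, n_nodes, gamma)
    ]
    return float(np.mean(densities))


def long_period_heights(
    seed: int,
    gamma: float = 1.9,
    period: int = 60,
    n_networks: int = 10,
    n_ics: int = 12,
    n_nodes: int = 1000,
    max_steps: int = 10_000,
):
    """Heights of attractors reached under very slow driving (T > 2 t_relax).

    Uses the time-independent (bare-state) recurrence — under slow driving
    the trajectory loops on a ground cycle within each half-period and that
    loop is the attractor the network is visibly on — and measures each
    state's height with the hub stopped at its current value.  Returns
    ``(heights, n_nonconverged)``.
    """
    rngs = child_rngs(seed, "topology", "ics")
    forcing = ForcingProtocol.driven(square_wave(period))
    heights = []
    n_bad = 0
    for net in _networks(rngs["topology"], n_networks, n_nodes, gamma):
        for _ in range(n_ics):
            res = run_to_attractor(
                net, random_state(n_nodes, rngs["ics"]), forcing,
                max_steps=max_steps, recurrence="state",
            )
            if isinstance(res, NonConvergence):
                n_bad += 1
                continue
            h = attractor_height(net, res, mode="stopped", max_steps=max_steps)
            if h is None:
                n_bad += 1
                continue
            heights.append(h)
    return heights, n_bad


def _signals_for(kind, lengths, rng, noise_length=200):
    if kind == "square":
        return [square_wave(T) for T in lengths]
    if kind == "pattern":
        return [repeated_pattern(T, rng) for T in lengths]
    if kind == "noise":
        return [white_noise(noise_length, rng) for _ in lengths]
    raise ValueError(f"unknown input kind {kind!r}")


def learning_run(
    seed: int,
    input_kind: str = "square",
    scheme: str = "driven",
    target_lengths=(6, 8, 10),
    n_nodes: int = 200,
    pop_size: int = 20,
    generations: int = 600,
    mutation_rate: float = 0.02,
    mutants_per_parent: int = 3,
    max_steps: int = 2000,
    gamma: float = 1.9,
):
    """One evolutionary run: multiplexed targets, chosen input kind and scheme."""
    rngs = child_rngs(seed, "topology", "signals", "evolution")
    population = _networks(rngs["topology"], pop_size, n_nodes, gamma)
    sig_rng = rngs["signals"]
    signals = _signals_for(input_kind, target_lengths, sig_rng)
    targets_fns = [random_target(L, sig_rng) for L in target_lengths]
    hubs = {net.hub for net in population}
    output_node = next(
        int(i) for i in sig_rng.permutation(n_nodes) if int(i) not in hubs
    )
    targets = TargetSet(pairs=tuple(zip(signals, targets_fns)), output_node=output_node)
    config = EvolutionConfig(
        pop_size=pop_size, mutants_per_parent=mutants_per_parent,
        mutation_rate=mutation_rate, generations=generations,
        max_steps=max_steps, scoring_scheme=scheme, seed=seed,
    )
    runner = evolve if scheme == "driven" else control_scheme_run
    return runner(population, targets, config, rngs["evolution"])


def tail_error(result, window: int = 10) -> float:
    """Mean best-network error over the last ``window`` generations."""
    return float(result.history["best_error"].tail(window).mean())


def mean_error(result) -> float:
    """Best-network error averaged over the whole run.

    A learning-speed summary: a scheme that converges quickly has a small
    area under its error curve even if a slow scheme eventually catches up.
    """
    return float(result.history["best_error"].mean())


def learning_comparison(
    seeds=(1, 2, 3),
    generations: int = 600,
    input_generations: int = 250,
    **kwargs,
) -> pd.DataFrame:
    """Resonant vs blocked-hub learning, plus the three input classes.

    Returns one row per (condition, seed) with the run's tail error.  The
    resonant-vs-control comparison runs ``generations`` learning cycles; the
    input-class comparison uses the shorter ``input_generations`` budget
    (the separation between periodic and aperiodic inputs appears early).
    """
    rows = []
    for seed in seeds:
        for label, kind, scheme, gens in [
            ("resonant", "square", "driven", generations),
            ("blocked", "square", "blocked", generations),
            ("square", "square", "driven", input_generations),
            ("pattern", "pattern", "driven", input_generations),
            ("noise", "noise", "driven", input_generations),
        ]:
            res = learning_run(
                seed, input_kind=kind, scheme=scheme, generations=gens, **kwargs
            )
            rows.append(
                {"condition": label, "seed": seed, "generations": gens,
                 "mean_error": mean_error(res), "tail_error": tail_error(res)}
            )
    return pd.DataFrame(rows)
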