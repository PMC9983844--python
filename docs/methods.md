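# Methods

## Model

A network has `N` nodes with binary states and directed weighted edges.  All
nodes update synchronously: node `i` takes the value 0 if the weighted sum of
its regulators' current states is negative, 1 if positive, and **keeps its
previous value on an exact tie** — which includes the common case of a node
whose regulators are all OFF (the sum is empty) and the rarer case of exact
cancellation.  Weights are i.i.d. uniform on `[−1, 1]`; an exact-zero draw is
redrawn so that a zero weight always means "no edge".  The asymmetry
parameter `α_w = mean(w)/std(w)` is 0 by construction here (balanced
activation and inhibition); the weight interval is constructor-exposed but no
shipped experiment changes it.

Topology: out-degrees are i.i.d. from the truncated power law
`P(k) = C·k^(−γ)`, `k ∈ {1, …, N−1}`, sampled by inverse CDF on the exact
normalized pmf.  Each node's targets are drawn uniformly without replacement
from the other nodes — no self-edges, no duplicate edges — so the in-degree
distribution is approximately Poisson with the same mean.  The hub is the
node of maximal out-degree; ties break to the lowest index so a seed fully
determines the network.  Mean degree falls steeply with γ (≈ 5.3 at γ = 1.9
and ≈ 1.4 at γ = 3.0 for N = 500–1000), which is what moves the family
across the order–chaos transition.

Hub forcing: `free` (hub follows the update rule), `blocked` (pinned to 0 or
1), or `driven` (hub follows a binary signal `I(t mod T)`, its incoming edges
ignored while forcing is active but retained in the structure).  The forcing
value at `t = 0` overwrites the initial state's hub bit.  Driving signals are
symmetric square waves (`T/2` ones then `T/2` zeros; odd periods are
rejected rather than approximated), repeated random patterns (constant
patterns rejected — they are a blocked hub in disguise), or fixed aperiodic
white-noise sequences.

## Attractor detection

Trajectories are simulated by a compiled (numba) kernel that carries the
state both as bytes and as a float vector (branch-free multiply-accumulate;
~3 µs/step at N = 200 and ~25 µs/step at N = 1000) and detects the first
recurrence with an open-addressing hash of the visited states.

Under periodic driving the map is time-dependent, so by default recurrence
is detected on the pair `(state, t mod T)`; the reported cycle is then a true
cycle whose length is a multiple of `T`, and the transient is exact.  The
time-independent alternative (`recurrence="state"`) stops at the first repeat
of the bare state; under slow driving this returns the ground cycle the
network is visibly looping on within one half-period, which is the natural
object for the "hub stops oscillating" height measurement, and it is the only
available notion under aperiodic inputs.  Both modes are verified bit-for-bit
against exhaustive enumeration of the full `2^N` transition graph (an
independent dense-matrix oracle) on networks up to N = 12, for blocked and
driven dynamics.

`max_steps` defaults to 10,000; exceeding it yields a typed non-convergence
outcome that callers count and exclude (scoring treats it as worst-case
error 1).

## Landscape quantities

* **Ground-state landscape**: attractors reached from random initial states
  with the hub blocked at 0 and at 1; duplicates merged by canonical
  rotation (lexicographically smallest `(state, phase)` pair leads).
* **Height** of a state: transient length of the blocked relaxation from it.
  A driven attractor's height averages its cycle states' heights with the
  hub stopped *at each state's own hub bit* (so cycles already sitting on
  ground cycles have height exactly 0); the variant that averages blocked-0
  and blocked-1 relaxations is also available (`mode="both"`) but charges
  even ground cycles for the opposite blocking's relaxation.
* **Relaxation time**: relax a random state under blocking `b`, flip to
  `1−b`, count steps to the new cycle; both directions alternate.
* **Novelty**: `1 − |A_T ∩ B| / |A_T|` on raw state sets.
* **Density**: distinct driven attractors (canonical rotation) divided by
  the number of initial conditions.
* **Order parameter**: flip `⌈dN⌉` distinct bits (never the hub while it is
  forced — a forced hub cannot hold a perturbation), co-evolve both
  trajectories `t_max = 300` steps and take the final normalized Hamming
  distance; traces plateau long before 300 steps at these sizes.

## Consequences of the keep-on-tie rule

The tie convention is not cosmetic.  A node whose input sum stays 0 — no
regulators, or regulators that are permanently OFF — never updates, so it
remembers its initial value forever.  Three measurable consequences, worth
knowing before interpreting results:

1. The perturbation order parameter has a nonzero floor even deep in the
   ordered phase (≈ 0.03–0.04 at γ ≥ 2.2, N = 500): flips landing on
   tie-frozen nodes never heal.  The ⟨h⟩-vs-γ curve is therefore U-shaped —
   healing improves toward γ ≈ 2, then chaotic spreading takes over — and
   the transition locator references its threshold (0.02) to the ordered-
   plateau floor rather than to zero, interpolating the crossing linearly.
   Measured this way the free-hub and driven-hub curves locate the
   transition at γ ≈ 1.8 and ≈ 1.7 respectively (both reach the same
   chaotic plateau, see below).
2. The chaotic plateau of ⟨h⟩ is ≈ 0.2, not 0.5, because a large fraction
   of nodes freeze; under this rule the plateau is reached for γ ≲ 1.4, so
   the chaotic-regime measurement is evaluated at γ = 1.3.
3. In roughly a quarter of γ = 1.9 networks, a large permanently-OFF core
   makes many nodes tie-frozen, and every random initial condition imprints
   those bits onto the driven attractor: such networks report a
   landscape density near 1 even though their *dynamical* cycle structure is
   small.  The ensemble density distribution is strongly bimodal (median
   ≈ 0.03, mean ≈ 0.25–0.33).

## Spectra

Node spectra are raw boxcar periodograms (`scipy.signal.periodogram`,
mean-removed, density scaling) of the node's cycle sequence tiled by whole
cycles to at least 512 samples — whole-cycle tiling guarantees leakage-free
lines, and the total power equals the sequence variance exactly (tested).
The dominant frequency excludes the DC bin and is undefined (NaN) for frozen
nodes.  The resonance map stacks the non-frozen nodes' spectra, rescales
frequency by the input frequency `N₀ = 1/T` and normalizes each row to unit
maximum.

## Evolutionary learning

Score of one (input, target) pair: run from a fresh random initial state to
the driven attractor, take the output node's cycle sequence, and minimize
the normalized Hamming distance over all circular rotations of the target.
Output and target sequences are compared on their full periodic extensions
(both tiled to `lcm(L, L_c)`).  A truncating variant that tiles to
`min(L, L_c)` is available (`comparison="truncate"`) but is not the default:
for a fixed-point attractor (`L = 1`, the typical blocked-hub outcome) the
one-sample comparison plus the rotation minimum scores *any* non-constant
target as a perfect match, which would trivialize the comparison between
driven and blocked learning.  Aggregate fitness over `M` pairs is
`1 − mean_i(h_i²)`.

Mutation hits each node independently with probability `μ = 0.02`; a hit
node picks one outgoing edge uniformly and either redraws its weight or
redirects it to a fresh target (no self-edge, no duplicate; a saturated
out-neighbourhood falls back to a weight change), so the out-degree sequence
— and hence the scale-free topology and the hub — is exactly conserved.
Selection keeps the best `N_pop` of the `(1 + 3)·N_pop` parents-plus-mutants,
ties broken parents-first then by index, so a run is exactly reproducible
from its seed.  Parents are re-scored every generation with fresh initial
conditions; a `fixed_scoring_ics` mode freezes the scoring states, making
the best fitness provably non-decreasing (used as a property test).

Control schemes replace the period-coded inputs: the hub is blocked at a
constant (1 by default) or left free, and the `M` cases are distinguished by
`M` fixed predefined initial conditions.  White-noise inputs use fixed
length-200 sequences — long enough that no periodicity is seen within a
typical transient — and are scored with bare-state recurrence since no input
phase exists.

## Ensemble sizes and defaults

Library defaults follow the headline settings: `N = 500`, `γ = 1.9`,
`μ = 0.02`, `N_pop = 50`, 3 mutants per parent, `d = 0.05`, `t_max = 300`,
1,000 initial conditions for landscape sampling, `max_steps = 10,000`.  The
shipped experiment protocols (`resonet.experiments`) and the acceptance
script run scaled-down ensembles chosen once for single-CPU runs:

* relaxation times: 12 networks × 10 trials, N = 1000;
* chaotic order parameter: 10–12 networks × 5 initial conditions, N = 500,
  γ = 1.3, t_max = 300;
* transition curves: γ grid 1.5–3.0 step 0.1, 12–16 networks × 5 initial
  conditions per point, free and T = 10 driven;
* landscape density: 5–10 networks × 300 initial conditions, N = 1000,
  T = 4;
* slow-driving heights: 9–10 networks × 12 initial conditions, T = 60;
* learning comparison: N = 200, `N_pop = 20`, G = 600 for the
  resonant-vs-blocked comparison and G = 250 for the input-class comparison
  (the orderings are decisive well before convergence), summarized by the
  error averaged over the identical generation budget.

## What the generators do and do not emulate

All inputs are synthetic by design — the model *is* the study object.  The
generators reproduce the statistical structure the analyses rely on
(power-law out-degree with Poisson in-degree, balanced continuous weights,
deterministic threshold dynamics, binary periodic/aperiodic inputs).  They
do not emulate features of real regulatory networks such as degree
correlations, autoregulation, combinatorial (non-additive) logic, noise in
updates, or asynchronous timing — conclusions about those require different
models.  Passing tests certify the implementation and the model-family
claims at the stated ensemble sizes, not biological generality.

## Known limitations

* Quantities that hinge on tie-frozen memory (order-parameter floor,
  density bimodality, occasional nonzero heights at very long driving
  periods — a period-60 orbit containing inter-flip transition states
  appears in ~1–2% of trials) are sensitive to the tie convention; a
  zero-on-tie variant of the rule would remove the memory effects but is a
  different model from the one implemented here.
* Exhaustive oracles certify N ≤ 12; larger networks rely on the property
  suite (cycle re-verification, determinism, blocked-hub invariance).
* Basin-size distributions and analytic mean-field transition curves are
  out of scope.
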