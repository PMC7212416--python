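# Methods

## Model and dynamics

The bundled network has 46 Boolean nodes: a 30-node activation core and four
differentiation modules. Rules are data (`src/tcellnet/data/cd4_model.bnet`,
BoolNet "targets, factors" dialect, with metadata in `cd4_meta.json`), not
code, and are stored verbatim in their compacted form — redundant shapes such
as `Ca or (Ca and Akt)` are kept as written and only collapsed inside the
reduction machinery, so the shipped file stays diffable against its source
table.

Updates are synchronous by default: x_i(t+1) = F_i(x(t)) for every non-input
node simultaneously. The asynchronous scheme updates the non-input nodes one
at a time in a seeded random permutation, one full sweep per step. Because
the fixed-point condition x = F(x) does not involve update timing, both
schemes share one attractor set; basin sizes, however, are scheme-dependent,
and all basin accounting in this package is synchronous only. Asynchronous
basin sizes depend on the arbitrary choice of per-node delays, which a
Boolean frame cannot pin down, so the asynchronous engine is exposed for
exploration but carries no reported numbers.

Input nodes (CD80/86, AMPK, and the six exogenous cytokines) are clamped:
they hold their initial value under every scheme. The TCR node is *not* an
input — its rule `TCR and not CTLA4dim` is a latch that stays on only until
CTLA-4 dimers appear. The antigen context of a run is therefore the initial
value of the TCR latch.

## Fixed points

Two independent routes enumerate the solutions of x = F(x):

* exhaustive: all 2^n states evaluated bit-parallel in numpy (bounded at 22
  nodes; states are swept in chunks of 2^20);
* solver: the conjunction of per-node equivalences x_i ↔ F_i(x) handed to a
  DPLL all-solutions search (sympy). Models that omit don't-care variables
  are expanded both ways.

The two routes are cross-checked against each other on random networks in
the test suite; results are sorted by bit pattern so enumeration order is
deterministic. Input nodes are free variables, so every fixed point records
its input values — the same internal pattern under AMPK = 0 and AMPK = 1
counts as two attractors.

## The hybrid CTLA-4/CD28 competition

The stimulatory capacity of CD80/86 is continuous, c(t) ∈ [0, 1], with
anticorrelated CTLA-4-dimer linkage 1 − c(t). Its closed form is the falling
sigmoid c(t) = 1/(exp(β(t − t_d)) + 1) with c(t_d) = 1/2. The consistent
differential form is dc/dt = −β c (1 − c); a variant with the opposite
(growing) sign is available behind a flag for comparison, but the decaying
form is authoritative here because the affinity shift runs from CD28 toward
the higher-affinity dimers, never back. The closed form is evaluated
analytically on the integer step grid (one discrete update = one continuous
time unit); a fixed-step RK4 integrator exists only to validate the closed
form in tests.

Defaults: β = 50 (effectively a step switch; no grid value falls strictly
between 0.01 and 0.99 except within 0.2 steps of t_d), t_d = 10 steps,
θ = 0.5 with ties discretized to 1 (c ≥ θ). The constraint t_d ≥ t_ac —
shutdown must not precede activation completion — is checked post hoc
against the measured t_ac (first step with IL2G, AP1, NFAT, NFKB all on;
t_ac = 8 for the bundled core from a resting start) and reported as a
warning, not an error.

Gating: by default the decay clock runs from simulation start ("clock"
mode), matching the fixed-t_d formulation. A "ctla4" mode holds c = 1 until
the CTLA4dim node first fires and starts the clock there; with the bundled
rules that gate never opens while the ligand is bound (dimers require free
CD80/86), so the mode exists for model variants rather than the shipped
rule set.

## Functional-state classification

Labels, in precedence order: Th1/Th2/Th17/Treg (lineage transcription factor
plus endogenous cytokine(s) all active: T-bet+IFN-γ, GATA3+IL-4,
RORγt+IL-21, Foxp3+IL-10+TGF-β) → activation (IL2G, AP1, NFAT, NFKB all on)
→ checkpoint → anergy → no-activation.

Two notions need care because they are *historical*, not state-local:

* **Checkpoint.** The arrest state after CTLA-4 dimers capture CD80/86 is,
  as a bare state vector, indistinguishable from a resting state. At the
  attractor level the label therefore requires that the hybrid shutdown
  actually fired during the run that produced the attractor. At the
  trajectory level (basin accounting, where no hybrid dynamics runs) it is
  assigned contextually: runs that start with both the TCR latch and the
  CD80/86 input on but end with every activation marker off.
* **Anergy routes.** All anergy fixed points (TCR on, Ndrg1 on, IL-2 off,
  NFAT/NF-κB still on, AP-1 off) require the CD80/86 input to be absent, so
  the two routes cannot be told apart by the final state or the input
  clamps. The basin classifier splits them by the initial CD28 bit:
  costimulatory receptor initially engaged but not sustained
  (`anergy_no_cd28`) versus never engaged (`anergy_tcr_only`). At the
  attractor level, where no initial condition exists, the canonical anergy
  pair carries the `anergy_no_cd28` label.

## Attractor census

`enumerate_model_attractors` counts attractors as (state, context) pairs,
where the context is the input combination under which the attractor was
found (antigen context = initial TCR). It unions three parts:

1. core fixed points reachable under each of the 8 contexts (TCR₀, CD80/86,
   AMPK; exogenous cytokines absent) — reachability is established from a
   probe ensemble containing the resting internal state, every combination
   of the six feedback-seeding nodes of the CTLA-4 arm, and 2048 seeded
   random internal states, iterated bit-parallel to convergence (the census
   is seed-independent in the tests because every reachable basin on this
   model is far too large to miss);
2. the terminal attractor of each phenotype scenario (Th1, Th2, Th17, Treg);
3. the terminal attractor of the checkpoint (hybrid shutdown) run under both
   AMPK states.

This yields 18 attractors for the bundled model: 8 no-activation (resting
and costimulation-only contexts, plus contexts whose TCR latch was
extinguished by initially present CTLA-4 dimers), 2 activation, 2 anergy,
2 checkpoint (differing only in AMPK), and the four effector phenotypes.

## Basins

Exhaustive basin sweeps are bounded at 24 nodes; the 30-node core is sampled
with uniform random initial states (seeded generator, default 10^6 samples in
the reproduction script), reporting binomial standard errors per class.
Samples are grouped on (classification-relevant initial bits, final state)
before classification, so the Python-level classifier runs once per group.
Trajectories that have not reached a fixed point within 4n synchronous steps
are counted separately as cycle-trapped; on the bundled core every sampled
trajectory converges within 2n steps.

For desk-scale exact cross-checks the core can be reduced to 12 nodes
(inputs plus the nodes closing all feedback loops: TCR, CD28, IL2G, CD25,
CTLA4, CTLA4dim, NDRG1, AP1, NFAT, AKT). The reduction preserves the
attractor set exactly (verified at construction) but *not* basin masses —
eliminating a node collapses its one-step delay, which shifts transient
routes between basins — so reduced-network basins are a qualitative check,
not a substitute for sampling the full core.

## Symbolic reduction

`steady_state_solve` derives each node's fixed-point value over chosen root
variables (for the core: TCR, CD28, AMPK). Feed-forward nodes are closed by
iterated substitution (only already-closed expressions are substituted, so
the pass terminates and cannot blow up around loops), with the derivation
trace recorded. Nodes entangled in feedback — including implicit inversions
such as CD80/86 = CD28, which no forward substitution can produce — are
resolved exactly from the enumerated fixed-point table: per root
combination the node's value must be unique, and a minimal DNF is fitted
(Quine–McCluskey; unrealized root combinations become don't-cares). A node
taking two values under one root combination is flagged cyclic rather than
guessed.

`reduce_network` eliminates nodes by substituting their rules into their
targets. The eliminated set must be acyclic among itself (a loop would carry
state that substitution discards; offending loops are reported by name,
self-loops immediately). Retained rules are re-minimized, and the reduction
is accepted only if the fixed points of the reduced network project onto
exactly the original's (exhaustive up to 22 nodes, SAT above). Minimization
is Quine–McCluskey up to 12 variables and flattening/absorption rewriting
beyond, always truth-table-equivalent.

## Synthetic networks

`random_network(n, k, seed)` draws, per node, up to k regulators and a
random conjunction/disjunction of possibly negated literals (occasionally a
constant; ~15 % of nodes become clamped inputs). It emulates the sparse,
shallow rule shapes of curated signaling models — it does not emulate their
degree distribution, feedback structure or canalization, so property tests
on random networks certify the *engine* (enumeration exactness, scheme
invariance, reduction soundness), not biological plausibility.

## Problem sizes and numerics

Exhaustive fixed-point enumeration is bounded at 22 nodes and exhaustive
basins at 24 (bit-parallel chunks of ≤ 2^20 states); the test suite uses
random networks of ≤ 12 nodes for dual-route checks and 10^5-scale Monte
Carlo for basin agreement, and the reproduction script uses 10^6 samples.
The logistic is evaluated overflow-safely (exp argument capped; the t → ∞
tail returns exp(−arg)). RK4 validation of the closed form starts from
exactly representable points (c = 1/2, or moderate β), because near the
repelling endpoint c = 1 the float truncation of 1 − ε is amplified by
e^{βt} regardless of integrator accuracy. Ties at the discretization
threshold go to 1.

## Known limitations

* The shipped rules are the compacted form of the model; the authors'
  original, un-compacted rule set has the same attractors but a richer
  transient structure, so basin masses computed here reflect the compacted
  dynamics only (the activation basin of the compacted core, for instance,
  is exactly 1/8: once CD80/86 is clamped on, CTLA-4 dimers can exist only
  at t = 0, so activation is decided by three initial bits).
* Checkpoint and anergy-route labels are historical notions resolved by
  convention (see above); alternative conventions change class bookkeeping
  but not the underlying attractors.
* Asynchronous basins and delay distributions are out of scope; SBML-qual
  import is a documented extension point, not implemented.
* The census' reachability step is sampling-based (with deterministic probe
  states for the known feedback seeds); on models with basins comparable in
  size to the probe ensemble it could in principle miss an attractor.
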