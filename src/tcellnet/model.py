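"""The bundled 46-node CD4 T-cell activation model.

The model couples a 30-node activation core — TCR and CD28 proximal
signaling, the IL-2/CD25 positive feedback, the Ndrg1 anergy circuit, the
CTLA-4 checkpoint and the AMPK/mTOR metabolic switch — with four
cytokine-driven differentiation modules (Th1, Th2, Th17, Treg).  The rules
are data, shipped as a BoolNet-dialect file plus a JSON metadata file, not
code.

Functional states
-----------------
Fixed points are classified into mutually exclusive labels, in precedence
order: the four effector phenotypes (lineage transcription factor plus
endogenous cytokine(s) active), ``activation`` (IL2G, AP1, NFAT and NFKB all
active), ``checkpoint``, the two anergy labels, and ``no_activation``.

The checkpoint is a time-extended notion: the arrest state reached after
CTLA-4 dimers outcompete CD28 on CD80/86.  At the attractor level the label
therefore requires that the hybrid affinity shutdown actually fired; at the
trajectory level (basin accounting) it is assigned contextually, to runs that
start with both the antigen (TCR) and costimulatory (CD80/86) context present
yet end with every activation marker off.

Anergy — Ndrg1 active, IL-2 off, with NFAT and NFKB still on — is split into
two routes by whether CD28 was initially engaged: ``anergy_no_cd28`` (the
costimulatory receptor was engaged but its signaling was not sustained) and
``anergy_tcr_only`` (no costimulation at all).  At the attractor level,
where no initial condition exists, the canonical anergy fixed point (TCR on,
CD28 off) carries the ``anergy_no_cd28`` label.

Attractor identity includes the input combination under which the attractor
was found (antigen context = the initial value of the latching TCR node), so
the same internal pattern under two AMPK values counts as two attractors.
"""

from __future__ import annotations

import importlib.resources
import itertools
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .hybrid import HybridSpec, HybridTrace, hybrid_simulate
from .network import (
    Network,
    Trajectory,
    find_fixed_points,
    parse_rules,
    restrict,
    simulate,
    with_rules,
)

__all__ = [
    "CD4Model",
    "Attractor",
    "ScenarioResult",
    "CLASS_LABELS",
    "build_model",
    "classify",
    "run_scenario",
    "enumerate_model_attractors",
    "NotAFixedPointError",
]

CLASS_LABELS = (
    "no_activation",
    "activation",
    "anergy_tcr_only",
    "anergy_no_cd28",
    "checkpoint",
    "Th1",
    "Th2",
    "Th17",
    "Treg",
)


class NotAFixedPointError(ValueError):
    """classify() requires a fixed point of the model."""


@dataclass(frozen=True)
class CD4Model:
    """Bundled model: full 46-node network, 30-node core, and metadata."""

    full: Network
    core: Network
    meta: Mapping

    @property
    def activation_markers(self) -> tuple[str, ...]:
        return tuple(self.meta["activation_markers"])

    @property
    def phenotype_markers(self) -> Mapping[str, Sequence[str]]:
        return self.meta["phenotype_markers"]

    @property
    def scenario_names(self) -> tuple[str, ...]:
        return tuple(self.meta["scenarios"])


@dataclass(frozen=True)
class Attractor:
    """A fixed point, the input combination under which it was found, and its
    functional-state label."""

    state: tuple[int, ...]
    names: tuple[str, ...]
    context: tuple[tuple[str, int], ...]
    label: str
    scenario: str | None = None

    def state_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.state))

    def context_dict(self) -> dict[str, int]:
        return dict(self.context)


@dataclass
class ScenarioResult:
    name: str
    trajectory: Trajectory
    label: str
    hybrid_trace: HybridTrace | None = None
    t_ac: int | None = None

    @property
    def final(self) -> dict:
        return self.trajectory.final


def _load_text(fname: str) -> str:
    return (
        importlib.resources.files("tcellnet")
        .joinpath("data")
        .joinpath(fname)
        .read_text(encoding="utf-8")
    )


def build_model() -> CD4Model:
    """Load and self-validate the bundled model."""
    meta = json.loads(_load_text("cd4_meta.json"))
    full = parse_rules(_load_text("cd4_model.bnet"), hybrid=meta["hybrid_node"])
    core_nodes = meta["core_nodes"]
    missing = [n for n in core_nodes if n not in full.names]
    if missing:
        raise ValueError(f"packaging error: core nodes missing from rules: {missing}")
    core = restrict(full, core_nodes)
    if core.n_nodes != 30 or full.n_nodes != 46:
        raise ValueError(
            f"packaging error: expected 30 core / 46 total nodes, got "
            f"{core.n_nodes}/{full.n_nodes}"
        )
    declared_inputs = set(meta["input_nodes"])
    if set(full.inputs) != declared_inputs:
        raise ValueError(
            f"packaging error: rule-file inputs {sorted(full.inputs)} do not "
            f"match metadata {sorted(declared_inputs)}"
        )
    return CD4Model(full=full, core=core, meta=meta)


def _all_markers(state: Mapping[str, int], markers: Sequence[str]) -> bool:
    return all(state.get(m, 0) for m in markers)


def classify(
    state: Mapping[str, int],
    context: Mapping[str, int] | None = None,
    *,
    model: CD4Model | None = None,
    hybrid_fired: bool = False,
    mode: str = "attractor",
    cd28_initial: int | None = None,
    check_fixed_point: bool = True,
) -> str:
    """Functional-state label of a fixed point.

    ``context`` carries the input combination (including the antigen context
    as key ``TCR``).  ``mode`` selects the checkpoint rule: ``"attractor"``
    requires ``hybrid_fired``; ``"trajectory"`` assigns checkpoint to runs
    with TCR and CD8086 context initially present.  ``cd28_initial`` feeds the
    anergy-route split in trajectory mode.
    """
    model = model or build_model()
    context = dict(context or {})
    if check_fixed_point:
        net = model.full if all(n in state for n in model.full.names) else model.core
        from .network import step_sync

        probe = {n: state[n] for n in net.names}
        nxt = step_sync(net, probe)
        # clamped-override scenarios may hold arbitrary nodes fixed
        held = {n for n, v in context.items() if n in net.names}
        if any(nxt[n] != probe[n] for n in net.names if n not in held):
            raise NotAFixedPointError(
                "state is not a fixed point of the model (pass "
                "check_fixed_point=False for transient states)"
            )
    for label, markers in model.phenotype_markers.items():
        if all(m in state for m in markers) and _all_markers(state, markers):
            return label
    if _all_markers(state, model.activation_markers):
        return "activation"
    markers_off = not any(state.get(m, 0) for m in model.activation_markers)
    tcr_ctx = context.get("TCR", state.get("TCR", 0))
    costim_ctx = context.get("CD8086", state.get("CD8086", 0))
    if markers_off:
        if mode == "attractor" and hybrid_fired and tcr_ctx:
            return "checkpoint"
        if mode == "trajectory" and tcr_ctx and costim_ctx:
            return "checkpoint"
    if state.get("TCR", 0) and state.get("NDRG1", 0) and not state.get("IL2G", 0):
        if mode == "trajectory":
            if cd28_initial is None:
                cd28_initial = context.get("CD28", 0)
            return "anergy_no_cd28" if cd28_initial else "anergy_tcr_only"
        return "anergy_no_cd28"
    return "no_activation"


def _scenario_network(model: CD4Model, cfg: Mapping) -> tuple[Network, dict]:
    """Network (with clamps applied) and initial state for a scenario."""
    net = model.full
    clamps: dict[str, int] = dict(cfg.get("clamp", {}))
    if clamps:
        net = with_rules(net, {n: None for n in clamps})
    init = {n: 0 for n in net.names}
    for n, v in cfg.get("inputs", {}).items():
        init[n] = int(v)
    for n in cfg.get("init_active", []):
        init[n] = 1
    for n, v in clamps.items():
        init[n] = int(v)
    return net, init


def run_scenario(
    name: str,
    model: CD4Model | None = None,
    ampk: int | None = None,
    spec: HybridSpec | None = None,
    max_steps: int = 200,
) -> ScenarioResult:
    """Run one of the named in-silico experiments to its attractor."""
    model = model or build_model()
    try:
        cfg = model.meta["scenarios"][name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(model.scenario_names)}"
        ) from None
    net, init = _scenario_network(model, cfg)
    if ampk is not None:
        init["AMPK"] = int(ampk)
    context = {**cfg.get("inputs", {}), **cfg.get("clamp", {}), "TCR": 1}
    context["AMPK"] = init["AMPK"]
    hybrid_fired = bool(cfg.get("hybrid", False))
    if hybrid_fired:
        init[net.hybrid] = 1
        traj, trace, t_ac = hybrid_simulate(
            net, init, spec=spec or HybridSpec(), max_steps=max_steps
        )
        context["CD8086"] = 1
        label = classify(
            traj.final,
            context,
            model=model,
            hybrid_fired=True,
            mode="attractor",
            check_fixed_point=False,
        )
        return ScenarioResult(name, traj, label, hybrid_trace=trace, t_ac=t_ac)
    traj = simulate(net, init, scheme="sync", max_steps=max_steps)
    label = classify(
        traj.final,
        context,
        model=model,
        mode="attractor",
        check_fixed_point=not traj.converged,
    )
    return ScenarioResult(name, traj, label)


def _reachable_fixed_points(
    net: Network,
    clamps: Mapping[str, int],
    tcr0: int,
    seed: int,
    n_probe: int = 2048,
) -> list[tuple[int, ...]]:
    """Distinct fixed points reached from a probe ensemble of initial states.

    The ensemble contains the all-off internal state, every combination of
    the feedback-seeding nodes (the CTLA-4 arm, which decides whether the TCR
    latch survives), and seeded random internal states.  Synchronous
    iteration, vectorized.
    """
    rng = np.random.default_rng(seed)
    idx = {n: i for i, n in enumerate(net.names)}
    free = [n for n in net.names if n not in clamps and n != "TCR"]
    seeds_nodes = [n for n in ("CTLA4dim", "CTLA4", "IL2G", "ZAP70", "NFAT", "AP1")
                   if n in idx and n in free]
    combos = list(itertools.product((0, 1), repeat=len(seeds_nodes)))
    n_states = len(combos) + n_probe
    states = np.zeros((n_states, net.n_nodes), dtype=bool)
    states[len(combos):, :] = rng.integers(0, 2, size=(n_probe, net.n_nodes), dtype=np.int8).astype(bool)
    for i, combo in enumerate(combos):
        for n, v in zip(seeds_nodes, combo):
            states[i, idx[n]] = bool(v)
    for n, v in clamps.items():
        states[:, idx[n]] = bool(v)
    states[:, idx["TCR"]] = bool(tcr0)
    step = net.compile_batch()
    for _ in range(4 * net.n_nodes):
        nxt = step(states)
        if (nxt == states).all():
            break
        states = nxt
    uniq = np.unique(states, axis=0)
    settled = (step(uniq) == uniq).all(axis=1)
    return [tuple(int(b) for b in row) for row in uniq[settled]]


def enumerate_model_attractors(
    model: CD4Model | None = None,
    seed: int = 0,
    n_probe: int = 2048,
) -> list[Attractor]:
    """The model's attractor census.

    Union of (a) the fixed points of the activation core reachable under each
    combination of the free context inputs (antigen context TCR0, CD8086,
    AMPK; exogenous cytokines absent), (b) the terminal attractor of each of
    the four phenotype scenarios, and (c) the terminal attractor of the
    CTLA-4 shutdown (checkpoint) scenario under both AMPK states.
    De-duplicated on (state, context); deterministic ordering.
    """
    model = model or build_model()
    net = model.full
    exo = [n for n in net.inputs if n not in ("CD8086", "AMPK")]
    out: dict[tuple, Attractor] = {}

    def add(state_bits, context, label, scenario=None):
        ctx_t = tuple(sorted(context.items()))
        key = (state_bits, ctx_t)
        if key not in out:
            out[key] = Attractor(state_bits, net.names, ctx_t, label, scenario)

    for tcr0, b, a in itertools.product((0, 1), repeat=3):
        clamps = {n: 0 for n in exo}
        clamps.update({"CD8086": b, "AMPK": a})
        context = dict(clamps)
        context["TCR"] = tcr0
        for bits in _reachable_fixed_points(net, clamps, tcr0, seed, n_probe):
            state = dict(zip(net.names, bits))
            label = classify(
                state, context, model=model, mode="attractor",
                check_fixed_point=False,
            )
            add(bits, context, label)

    for scen in ("th1", "th2", "th17", "treg"):
        res = run_scenario(scen, model=model)
        bits = tuple(int(res.final[n]) for n in net.names)
        cfg = model.meta["scenarios"][scen]
        context = {n: 0 for n in exo}
        context.update(cfg["inputs"])
        context["TCR"] = 1
        add(bits, context, res.label, scenario=scen)

    for a in (0, 1):
        res = run_scenario("checkpoint", model=model, ampk=a)
        bits = tuple(int(res.final[n]) for n in net.names)
        context = {n: 0 for n in exo}
        context.update({"CD8086": 1, "AMPK": a, "TCR": 1})
        add(bits, context, res.label, scenario="checkpoint")

    return sorted(out.values(), key=lambda at: (at.context, at.state))
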