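"""Boolean networks, update schemes, trajectories and exact fixed points.

A :class:`Network` is an ordered set of named nodes, each carrying an update
rule or marked as an input.  Input nodes are clamped: they keep whatever value
the initial state gives them under every update scheme.  A node whose rule
mentions itself (e.g. a receptor that latches its own activity) is *not* an
input; it simply feeds back on itself.

States are plain ``dict[name -> 0/1]`` in the public API; internally the
module compiles a network once into a vectorized numpy update function so that
millions of trajectories can be iterated in parallel (used by the basin
machinery).

Fixed points ``x = F(x)`` are found either by exhaustive bit-parallel
enumeration (small networks) or with an all-solutions SAT search over the
conjunction of per-node equivalences (sympy's DPLL).  Input nodes are free
variables, so every fixed point records its input values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy
from sympy.logic.boolalg import And as SymAnd, Equivalent
from sympy.logic.inference import satisfiable

from .expr import (
    And,
    BoolExpr,
    Const,
    Not,
    Or,
    Var,
    evaluate,
    variables,
)
from .parse import ParsedRule, UndefinedNodeError, parse_rules_text

__all__ = [
    "Network",
    "Trajectory",
    "parse_rules",
    "step_sync",
    "step_async",
    "simulate",
    "find_fixed_points",
    "random_network",
    "SizeLimitError",
    "InvalidOrderError",
]

State = dict  # alias for readability: dict[str, int]

EXHAUSTIVE_NODE_LIMIT = 22


class SizeLimitError(ValueError):
    """Network too large for exhaustive enumeration; use the solver method."""


class InvalidOrderError(ValueError):
    """Asynchronous update order is not a permutation of the non-input nodes."""


@dataclass(frozen=True)
class Network:
    """An ordered Boolean network.

    Parameters
    ----------
    names : node names, in the order that defines state bit order.
    rules : mapping name -> rule; input nodes map to ``None``.
    hybrid : optional name of the node driven by a continuous variable.  The
        hybrid node must be input-like (no rule): its Boolean value is imposed
        by threshold discretization, never computed from a rule.
    """

    names: tuple[str, ...]
    rules: Mapping[str, BoolExpr | None]
    hybrid: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate node names")
        for name in self.names:
            if name not in self.rules:
                raise ValueError(f"no rule entry for node {name!r}")
        for name, rule in self.rules.items():
            if name not in self.names:
                raise ValueError(f"rule for undeclared node {name!r}")
            if rule is None:
                continue
            for ref in variables(rule):
                if ref not in self.names:
                    raise UndefinedNodeError(
                        f"rule for {name!r} references undefined node {ref!r}"
                    )
        if self.hybrid is not None:
            if self.hybrid not in self.names:
                raise ValueError(f"hybrid node {self.hybrid!r} not declared")
            if self.rules[self.hybrid] is not None:
                raise ValueError(
                    f"hybrid node {self.hybrid!r} must be input-like (no rule)"
                )

    # -- structure ---------------------------------------------------------
    @property
    def inputs(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.rules[n] is None)

    @property
    def regular(self) -> tuple[str, ...]:
        """Nodes with rules (everything that actually updates)."""
        return tuple(n for n in self.names if self.rules[n] is not None)

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    # -- state helpers -----------------------------------------------------
    def state_tuple(self, state: Mapping[str, int]) -> tuple[int, ...]:
        return tuple(1 if state[n] else 0 for n in self.names)

    def state_dict(self, bits: Sequence[int]) -> dict[str, int]:
        return {n: int(b) for n, b in zip(self.names, bits)}

    def validate_state(self, state: Mapping[str, int]) -> None:
        missing = [n for n in self.names if n not in state]
        if missing:
            raise KeyError(f"state is missing nodes: {missing}")

    # -- vectorized evaluation --------------------------------------------
    def compile_batch(self) -> Callable[[np.ndarray], np.ndarray]:
        """Compile the synchronous update into ``f(states) -> next_states``
        where ``states`` is a boolean array of shape (n_samples, n_nodes)."""
        idx = {n: i for i, n in enumerate(self.names)}

        def compile_expr(e: BoolExpr) -> Callable[[np.ndarray], np.ndarray]:
            if isinstance(e, Const):
                v = bool(e.value)
                return lambda s: np.full(s.shape[0], v, dtype=bool)
            if isinstance(e, Var):
                i = idx[e.name]
                return lambda s: s[:, i]
            if isinstance(e, Not):
                f = compile_expr(e.child)
                return lambda s: ~f(s)
            fs = [compile_expr(c) for c in e.children]
            if isinstance(e, And):
                def fand(s, fs=fs):
                    out = fs[0](s).copy()
                    for f in fs[1:]:
                        out &= f(s)
                    return out
                return fand
            def forr(s, fs=fs):
                out = fs[0](s).copy()
                for f in fs[1:]:
                    out |= f(s)
                return out
            return forr

        compiled = [
            (idx[n], compile_expr(self.rules[n])) for n in self.regular
        ]

        def step(states: np.ndarray) -> np.ndarray:
            nxt = states.copy()
            for i, f in compiled:
                nxt[:, i] = f(states)
            return nxt

        return step


def with_rules(
    net: Network, replacements: Mapping[str, BoolExpr | None]
) -> Network:
    """A copy of ``net`` with some rules replaced (``None`` turns a node into
    a clamped input).  Used for clamped-overexpression scenarios and for
    in-silico rule mutations."""
    unknown = [n for n in replacements if n not in net.names]
    if unknown:
        raise ValueError(f"unknown nodes: {unknown}")
    rules = dict(net.rules)
    rules.update(replacements)
    hybrid = net.hybrid
    if hybrid is not None and rules[hybrid] is not None:
        hybrid = None
    return Network(names=net.names, rules=rules, hybrid=hybrid)


def restrict(net: Network, keep: Sequence[str]) -> Network:
    """Subnetwork over ``keep`` (rules must not reach outside the kept set)."""
    keep_t = tuple(keep)
    rules = {n: net.rules[n] for n in keep_t}
    hybrid = net.hybrid if net.hybrid in keep_t else None
    return Network(names=keep_t, rules=rules, hybrid=hybrid)


@dataclass
class Trajectory:
    """A synchronous or asynchronous run, including its initial state."""

    states: list[dict]
    update_scheme: str
    seed: int | None = None
    converged: bool = False
    steps_to_attractor: int | None = None
    cycle_length: int | None = None

    @property
    def final(self) -> dict:
        return self.states[-1]

    def __len__(self) -> int:
        return len(self.states)


def parse_rules(text: str, hybrid: str | None = None) -> Network:
    """Parse rule text (either dialect) into a :class:`Network`."""
    parsed: list[ParsedRule] = parse_rules_text(text)
    names = tuple(p.name for p in parsed)
    # References resolve case-insensitively against the declared spelling
    # (Table-style rule text freely mixes e.g. "AKT" and "Akt").
    by_lower = {n.lower(): n for n in names}

    def canon(expr: BoolExpr) -> BoolExpr:
        if isinstance(expr, Var):
            return Var(by_lower.get(expr.name.lower(), expr.name))
        if isinstance(expr, Not):
            return Not(canon(expr.child))
        if isinstance(expr, And):
            return And(tuple(canon(c) for c in expr.children))
        if isinstance(expr, Or):
            return Or(tuple(canon(c) for c in expr.children))
        return expr

    rules = {p.name: (None if p.expr is None else canon(p.expr)) for p in parsed}
    # BoolNet marks inputs as self-identities; treat `X, X` as an input clamp.
    for p in parsed:
        if rules[p.name] == Var(p.name):
            rules[p.name] = None
    declared = set(names)
    for p in parsed:
        expr = rules[p.name]
        if expr is None:
            continue
        for ref in sorted(variables(expr)):
            if ref not in declared:
                raise UndefinedNodeError(
                    f"rule for {p.name!r} references undefined node {ref!r}",
                    p.line,
                )
    if hybrid is not None:
        hybrid = by_lower.get(hybrid.lower(), hybrid)
    return Network(names=names, rules=rules, hybrid=hybrid)


def step_sync(net: Network, state: Mapping[str, int]) -> dict:
    """One synchronous update: every non-input node recomputed simultaneously.

    Pure function: the input mapping is never mutated.  The hybrid node (if
    any) has no rule and is therefore carried over unchanged, i.e. treated as
    clamped at its current value.
    """
    net.validate_state(state)
    nxt = {n: (1 if state[n] else 0) for n in net.names}
    for n in net.regular:
        nxt[n] = evaluate(net.rules[n], state)
    return nxt


def step_async(
    net: Network,
    state: Mapping[str, int],
    order: Sequence[str] | None = None,
    seed: int | None = None,
) -> dict:
    """One asynchronous sweep: non-input nodes updated one at a time.

    Each update sees the effects of earlier updates in the same sweep.  Pass
    an explicit ``order`` (a permutation of the non-input nodes) or a ``seed``
    for a reproducible random permutation.
    """
    net.validate_state(state)
    regular = net.regular
    if order is None:
        rng = np.random.default_rng(seed)
        order = [regular[i] for i in rng.permutation(len(regular))]
    if sorted(order) != sorted(regular):
        raise InvalidOrderError(
            f"order must be a permutation of the non-input nodes {sorted(regular)}"
        )
    cur = {n: (1 if state[n] else 0) for n in net.names}
    for n in order:
        cur[n] = evaluate(net.rules[n], cur)
    return cur


def simulate(
    net: Network,
    init: Mapping[str, int],
    scheme: str = "sync",
    max_steps: int = 1000,
    seed: int | None = None,
) -> Trajectory:
    """Iterate until a fixed point, a revisited state (cycle), or max_steps.

    Non-convergence is a reported outcome (``converged=False`` with
    ``cycle_length`` set when a cycle was detected), never an error.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    net.validate_state(init)
    rng = np.random.default_rng(seed) if scheme == "async" else None
    cur = {n: (1 if init[n] else 0) for n in net.names}
    traj = Trajectory(states=[dict(cur)], update_scheme=scheme, seed=seed)
    seen: dict[tuple[int, ...], int] = {net.state_tuple(cur): 0}
    for t in range(1, max_steps + 1):
        if scheme == "sync":
            nxt = step_sync(net, cur)
        elif scheme == "async":
            regular = net.regular
            order = [regular[i] for i in rng.permutation(len(regular))]
            nxt = step_async(net, cur, order=order)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        if nxt == cur:
            traj.converged = True
            traj.steps_to_attractor = t - 1
            return traj
        traj.states.append(dict(nxt))
        key = net.state_tuple(nxt)
        if key in seen and scheme == "sync":
            traj.cycle_length = t - seen[key]
            return traj
        seen[key] = t
        cur = nxt
    return traj


def _sorted_states(net: Network, states: Iterable[tuple[int, ...]]) -> list[dict]:
    return [net.state_dict(bits) for bits in sorted(set(states))]


def _fixed_points_exhaustive(net: Network, chunk_bits: int = 20) -> list[dict]:
    n = net.n_nodes
    if n > EXHAUSTIVE_NODE_LIMIT:
        raise SizeLimitError(
            f"{n} nodes exceeds the exhaustive bound of {EXHAUSTIVE_NODE_LIMIT}; "
            "use method='solver'"
        )
    step = net.compile_batch()
    found: list[tuple[int, ...]] = []
    total = 1 << n
    chunk = 1 << min(chunk_bits, n)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        states = ((codes[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(bool)
        fixed = (step(states) == states).all(axis=1)
        for row in states[fixed]:
            found.append(tuple(int(b) for b in row))
    return _sorted_states(net, found)


def _fixed_points_solver(net: Network) -> list[dict]:
    symbols = {n: sympy.Symbol(n) for n in net.names}
    clauses = []
    for n in net.regular:
        from .expr import to_sympy

        clauses.append(Equivalent(symbols[n], to_sympy(net.rules[n], symbols)))
    formula = SymAnd(*clauses) if clauses else sympy.true
    models = satisfiable(formula, all_models=True)
    found: list[tuple[int, ...]] = []
    first = next(models, False)
    if first is False:
        return []
    for model in itertools.chain([first], models):
        base = {n: bool(model.get(symbols[n], False)) for n in net.names}
        # sympy omits don't-care symbols from a model: expand them both ways
        free = [n for n in net.names if symbols[n] not in model]
        for combo in itertools.product((0, 1), repeat=len(free)):
            s = dict(base)
            s.update(zip(free, combo))
            found.append(tuple(1 if s[n] else 0 for n in net.names))
    return _sorted_states(net, found)


def find_fixed_points(net: Network, method: str = "auto") -> list[dict]:
    """All solutions of ``x = F(x)``, deterministically ordered.

    ``method`` is ``"exhaustive"`` (bit-parallel sweep of all states, bounded
    at 22 nodes), ``"solver"`` (all-solutions SAT, unbounded) or ``"auto"``.
    """
    if method == "auto":
        method = "exhaustive" if net.n_nodes <= EXHAUSTIVE_NODE_LIMIT else "solver"
    if method == "exhaustive":
        return _fixed_points_exhaustive(net)
    if method == "solver":
        return _fixed_points_solver(net)
    raise ValueError(f"unknown method {method!r}")


def random_network(
    n_nodes: int,
    max_inputs_per_node: int = 3,
    seed: int | None = None,
    p_input: float = 0.15,
) -> Network:
    """Seeded random Boolean network for property testing.

    Each node draws up to ``max_inputs_per_node`` regulators and a random
    expression shape (a conjunction/disjunction of possibly negated literals,
    occasionally a constant).  A small fraction of nodes become clamped
    inputs.  Deterministic for a given seed.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    names = tuple(f"N{i}" for i in range(n_nodes))
    rules: dict[str, BoolExpr | None] = {}
    for name in names:
        if n_nodes > 1 and rng.random() < p_input:
            rules[name] = None
            continue
        k = int(rng.integers(1, max_inputs_per_node + 1))
        regs = [names[i] for i in rng.choice(n_nodes, size=min(k, n_nodes), replace=False)]
        lits: list[BoolExpr] = [
            Not(Var(r)) if rng.random() < 0.5 else Var(r) for r in regs
        ]
        if rng.random() < 0.05:
            rules[name] = Const(int(rng.integers(0, 2)))
        elif len(lits) == 1:
            rules[name] = lits[0]
        elif rng.random() < 0.5:
            rules[name] = And(tuple(lits))
        else:
            rules[name] = Or(tuple(lits))
    return Network(names=names, rules=rules)
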