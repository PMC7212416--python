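"""Symbolic steady-state analysis and attractor-preserving network reduction.

At a fixed point the update system becomes a set of Boolean algebraic
equations x_i = F_i(x).  Two symbolic operations are built on that view:

* :func:`steady_state_solve` expresses every node's fixed-point value as a
  minimal-DNF formula over a chosen set of *root* variables (typically the
  context inputs, e.g. TCR, CD28, AMPK) — the "steady state" column of a
  compacted rule table.
* :func:`reduce_network` eliminates nodes by substituting their rules into
  their targets, yielding a smaller network with the same fixed points when
  projected onto the retained nodes (verified, not assumed).

Minimization uses Quine–McCluskey (via sympy) up to a variable bound, and
conservative absorption/idempotence rewriting above it, so the result is
always logically equivalent to the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import sympy
from sympy.logic import boolalg as _ba

from .expr import (
    And,
    BoolExpr,
    Const,
    Not,
    Or,
    Var,
    evaluate,
    from_sympy,
    substitute,
    to_sympy,
    variables,
)
from .network import Network, find_fixed_points

__all__ = [
    "SymbolicSolution",
    "ReducedNetwork",
    "simplify",
    "steady_state_solve",
    "reduce_network",
    "EliminationLoopError",
    "ReductionEquivalenceError",
]

QM_VARIABLE_LIMIT = 12


class EliminationLoopError(ValueError):
    """Eliminated nodes form a feedback loop among themselves."""


class ReductionEquivalenceError(AssertionError):
    """The reduced network's projected fixed points differ from the original's."""


def _flatten(expr: BoolExpr) -> BoolExpr:
    """Cheap structural normalization: flatten nested And/Or, drop duplicate
    children, apply absorption and constant rules.  Equivalence-preserving."""
    if isinstance(expr, Not):
        child = _flatten(expr.child)
        if isinstance(child, Const):
            return Const(1 - child.value)
        if isinstance(child, Not):
            return child.child
        return Not(child)
    if not isinstance(expr, (And, Or)):
        return expr
    is_and = isinstance(expr, And)
    absorbing, identity = (Const(0), Const(1)) if is_and else (Const(1), Const(0))
    kids: list[BoolExpr] = []
    for c in expr.children:
        c = _flatten(c)
        if isinstance(c, type(expr)):
            kids.extend(c.children)
        else:
            kids.append(c)
    out: list[BoolExpr] = []
    seen = set()
    for c in kids:
        if c == absorbing:
            return absorbing
        if c == identity or c in seen:
            continue
        seen.add(c)
        out.append(c)
    # absorption: in an Or, drop an And-term that contains another child;
    # dually for And.
    def absorbed(c: BoolExpr) -> bool:
        other = And if not is_and else Or
        if isinstance(c, other):
            return any(k in seen and k != c for k in c.children)
        return False

    out = [c for c in out if not absorbed(c)]
    # complement pair => constant
    for c in out:
        if Not(c) in seen or (isinstance(c, Not) and c.child in seen):
            return absorbing
    if not out:
        return identity
    if len(out) == 1:
        return out[0]
    out.sort(key=str)
    return And(tuple(out)) if is_and else Or(tuple(out))


def simplify(expr: BoolExpr) -> BoolExpr:
    """Canonical minimal DNF (Quine–McCluskey) for expressions over at most
    12 variables; flattening/absorption rewriting above that bound."""
    nvars = len(variables(expr))
    flat = _flatten(expr)
    if nvars > QM_VARIABLE_LIMIT:
        return flat
    if isinstance(flat, Const):
        return flat
    symbols: dict[str, sympy.Symbol] = {}
    sym = to_sympy(flat, symbols)
    simplified = _ba.simplify_logic(sym, form="dnf", force=True)
    return from_sympy(simplified)


@dataclass
class SymbolicSolution:
    """Fixed-point expressions over the root variables, plus derivation trace."""

    roots: tuple[str, ...]
    expressions: dict[str, BoolExpr]
    trace: list[str] = field(default_factory=list)
    cyclic: tuple[str, ...] = ()

    def check(self, state: Mapping[str, int]) -> dict[str, bool]:
        """Evaluate each expression under the root values of ``state`` and
        compare with the node's actual value."""
        return {
            n: evaluate(e, state) == (1 if state[n] else 0)
            for n, e in self.expressions.items()
        }


def _substitution_pass(
    net: Network, roots: set[str], max_rounds: int
) -> tuple[dict[str, BoolExpr], list[str]]:
    """Iterated substitution toward the roots.

    A node closes once every regulator in its (flattened) rule is already
    closed over the roots; its own expression is then the simplified
    substitution.  Substituting only closed expressions keeps every
    intermediate formula over the root variables, so the pass terminates and
    cannot blow up around feedback loops — nodes entangled in feedback simply
    never close and keep their one-step rule for the caller to resolve.
    """
    exprs: dict[str, BoolExpr] = {}
    closed: set[str] = set()
    for n in net.names:
        if n in roots:
            exprs[n] = Var(n)
            closed.add(n)
        elif net.rules[n] is None:
            exprs[n] = Var(n)  # free input that is not a root: stays open
        else:
            exprs[n] = _flatten(net.rules[n])
            if isinstance(exprs[n], Const):
                closed.add(n)
    trace: list[str] = []
    for rnd in range(max_rounds):
        changed = False
        for n in net.names:
            if n in closed or net.rules[n] is None:
                continue
            deps = variables(exprs[n])
            if deps <= closed:
                sub = {v: exprs[v] for v in deps if v not in roots}
                if sub:
                    exprs[n] = simplify(substitute(exprs[n], sub))
                    trace.append(f"round {rnd}: {n} <= substituted {sorted(sub)}")
                else:
                    exprs[n] = simplify(exprs[n])
                closed.add(n)
                changed = True
        if not changed:
            break
    return exprs, trace


def steady_state_solve(
    net: Network,
    roots: Sequence[str],
    clamps: Mapping[str, int] | None = None,
    max_rounds: int | None = None,
) -> SymbolicSolution:
    """Express every node's fixed-point value over the ``roots``.

    Substitution toward the roots handles the feed-forward part of the
    network and records its trace.  Nodes entangled in feedback (their
    expression never closes onto the roots — including implicit relations
    such as an input that equals a root only *at* the fixed point) are
    resolved exactly from the enumerated fixed-point table: for every root
    combination realized by a fixed point the node's value must be unique,
    and a minimal DNF is fitted over the roots (unseen root combinations are
    don't-cares).  Nodes whose value is not a function of the roots are
    flagged cyclic rather than raising.

    ``clamps`` restricts the analysis to fixed points with the given input
    values (e.g. a differentiation module's exogenous cytokines set to 1).
    """
    if not roots:
        raise ValueError("roots must be non-empty")
    root_set = set(roots)
    unknown = root_set - set(net.names)
    if unknown:
        raise ValueError(f"unknown root nodes: {sorted(unknown)}")
    exprs, trace = _substitution_pass(net, root_set, max_rounds or 2 * net.n_nodes)

    closed: dict[str, BoolExpr] = {}
    open_nodes: list[str] = []
    for n in net.names:
        if n in root_set:
            closed[n] = Var(n)
        elif variables(exprs[n]) <= root_set:
            closed[n] = simplify(exprs[n])
        else:
            open_nodes.append(n)

    cyclic: list[str] = []
    if open_nodes:
        fps = find_fixed_points(net)
        if clamps:
            fps = [s for s in fps if all(s[k] == v for k, v in clamps.items())]
        if not fps:
            raise ValueError("no fixed points under the given clamps")
        root_list = sorted(root_set)
        table: dict[tuple[int, ...], dict[str, set[int]]] = {}
        for s in fps:
            key = tuple(s[r] for r in root_list)
            slot = table.setdefault(key, {n: set() for n in open_nodes})
            for n in open_nodes:
                slot[n].add(s[n])
        minterm_keys = sorted(table)
        dontcares = [
            list(k)
            for k in (tuple((m >> i) & 1 for i in range(len(root_list)))
                      for m in range(1 << len(root_list)))
            if k not in table
        ]
        syms = [sympy.Symbol(r) for r in root_list]
        for n in open_nodes:
            vals = {k: table[k][n] for k in minterm_keys}
            if any(len(v) != 1 for v in vals.values()):
                cyclic.append(n)
                trace.append(f"{n}: multiple fixed-point values per root combo")
                continue
            minterms = [list(k) for k in minterm_keys if vals[k] == {1}]
            sop = _ba.SOPform(syms, minterms, dontcares)
            closed[n] = from_sympy(sop)
            trace.append(f"{n} <= fitted over roots from {len(fps)} fixed points")

    return SymbolicSolution(
        roots=tuple(sorted(root_set)),
        expressions=closed,
        trace=trace,
        cyclic=tuple(cyclic),
    )


@dataclass
class ReducedNetwork:
    """A reduced network plus the map from eliminated nodes to expressions
    over the retained ones."""

    network: Network
    eliminated: dict[str, BoolExpr]


def _projected_fixed_points(net: Network, keep: Sequence[str]) -> set[tuple[int, ...]]:
    method = "exhaustive" if net.n_nodes <= 22 else "solver"
    fps = find_fixed_points(net, method=method)
    return {tuple(s[k] for k in keep) for s in fps}


def reduce_network(
    net: Network,
    keep: Sequence[str],
    verify: bool = True,
) -> ReducedNetwork:
    """Eliminate all nodes outside ``keep`` by substitution.

    ``keep`` must contain every input node and the hybrid node.  The
    eliminated nodes must not form a feedback loop among themselves (such a
    loop carries state that substitution cannot express); offending loops are
    reported by name.  After substitution each retained rule is re-minimized.
    The reduction is only returned if the fixed points of the reduced network
    project onto exactly the original's (checked exhaustively up to 22 nodes,
    with the SAT solver above).
    """
    keep_set = set(keep)
    unknown = keep_set - set(net.names)
    if unknown:
        raise ValueError(f"unknown nodes in keep: {sorted(unknown)}")
    for inp in net.inputs:
        if inp not in keep_set:
            raise ValueError(f"input node {inp!r} must be kept")
    if net.hybrid is not None and net.hybrid not in keep_set:
        raise ValueError(f"hybrid node {net.hybrid!r} must be kept")
    eliminated = [n for n in net.names if n not in keep_set]
    if not eliminated:
        return ReducedNetwork(network=net, eliminated={})

    dep = nx.DiGraph()
    dep.add_nodes_from(eliminated)
    for n in eliminated:
        for v in variables(net.rules[n]):
            if v in dep and v != n:
                dep.add_edge(v, n)
        if n in variables(net.rules[n]):
            raise EliminationLoopError(
                f"cannot eliminate self-referential node {n!r}"
            )
    try:
        order = list(nx.topological_sort(dep))
    except nx.NetworkXUnfeasible:
        loop = next(nx.simple_cycles(dep))
        raise EliminationLoopError(
            f"eliminated nodes form a feedback loop: {' -> '.join(loop)}"
        ) from None

    resolved: dict[str, BoolExpr] = {}
    for n in order:
        expr = substitute(net.rules[n], resolved)
        resolved[n] = _flatten(expr)

    kept_names = tuple(n for n in net.names if n in keep_set)
    new_rules: dict[str, BoolExpr | None] = {}
    for n in kept_names:
        rule = net.rules[n]
        if rule is None:
            new_rules[n] = None
        else:
            new_rules[n] = simplify(substitute(rule, resolved))
    reduced = Network(names=kept_names, rules=new_rules, hybrid=net.hybrid)

    if verify:
        orig = _projected_fixed_points(net, kept_names)
        red = _projected_fixed_points(reduced, kept_names)
        if orig != red:
            raise ReductionEquivalenceError(
                f"projected fixed points differ: only-original="
                f"{sorted(orig - red)}, only-reduced={sorted(red - orig)}"
            )
    return ReducedNetwork(network=reduced, eliminated=resolved)


#: Default retained nodes for the bundled activation core: the context inputs
#: plus the smallest set closing all feedback loops (the TCR latch, the
#: IL-2/CD25/PDK1/AKT loop, and the CTLA-4 arm).
CORE_RETAINED_12 = (
    "TCR", "CD8086", "AMPK", "CD28", "IL2G", "CD25",
    "CTLA4", "CTLA4dim", "NDRG1", "AP1", "NFAT", "AKT",
)
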