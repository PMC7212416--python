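"""Boolean expression trees.

A rule's right-hand side is a small AST over node names: constants, variables,
negation, and n-ary conjunction/disjunction.  Expressions are immutable and
hashable, so structural equality works out of the box; semantic (truth-table)
equality is a separate helper.  Conversion to and from :mod:`sympy` is provided
for the symbolic reduction machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator, Mapping

import sympy
from sympy.logic import boolalg as _ba

__all__ = [
    "BoolExpr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "TRUE",
    "FALSE",
    "evaluate",
    "variables",
    "substitute",
    "to_sympy",
    "from_sympy",
    "semantically_equal",
    "IncompleteStateError",
]


class IncompleteStateError(KeyError):
    """A variable required by an expression is missing from the state."""


class BoolExpr:
    """Base class for Boolean expression nodes."""

    __slots__ = ()

    def __and__(self, other: "BoolExpr") -> "BoolExpr":
        return And((self, other))

    def __or__(self, other: "BoolExpr") -> "BoolExpr":
        return Or((self, other))

    def __invert__(self) -> "BoolExpr":
        return Not(self)


@dataclass(frozen=True, slots=True)
class Const(BoolExpr):
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError(f"constant must be 0 or 1, got {self.value!r}")

    def __str__(self) -> str:
        return str(self.value)


@dataclass(frozen=True, slots=True)
class Var(BoolExpr):
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class Not(BoolExpr):
    child: BoolExpr

    def __str__(self) -> str:
        if isinstance(self.child, (Var, Const)):
            return f"not {self.child}"
        return f"not ({self.child})"


def _nary_post_init(self: "And | Or") -> None:
    if not isinstance(self.children, tuple):
        object.__setattr__(self, "children", tuple(self.children))
    if len(self.children) < 2:
        raise ValueError(f"{type(self).__name__} requires at least 2 children")


@dataclass(frozen=True, slots=True)
class And(BoolExpr):
    children: tuple[BoolExpr, ...]

    __post_init__ = _nary_post_init

    def __str__(self) -> str:
        return " and ".join(
            f"({c})" if isinstance(c, Or) else str(c) for c in self.children
        )


@dataclass(frozen=True, slots=True)
class Or(BoolExpr):
    children: tuple[BoolExpr, ...]

    __post_init__ = _nary_post_init

    def __str__(self) -> str:
        return " or ".join(str(c) for c in self.children)


TRUE = Const(1)
FALSE = Const(0)


def evaluate(expr: BoolExpr, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` under a complete assignment of node values.

    Standard Boolean semantics; returns 0 or 1 and never mutates ``state``.
    Raises :class:`IncompleteStateError` if a referenced variable is missing.
    """
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Var):
        try:
            return 1 if state[expr.name] else 0
        except KeyError:
            raise IncompleteStateError(
                f"state is missing a value for node {expr.name!r}"
            ) from None
    if isinstance(expr, Not):
        return 1 - evaluate(expr.child, state)
    if isinstance(expr, And):
        for c in expr.children:
            if not evaluate(c, state):
                return 0
        return 1
    if isinstance(expr, Or):
        for c in expr.children:
            if evaluate(c, state):
                return 1
        return 0
    raise TypeError(f"not a BoolExpr: {expr!r}")


def variables(expr: BoolExpr) -> frozenset[str]:
    """The set of node names referenced by ``expr``."""
    out: set[str] = set()
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Var):
            out.add(e.name)
        elif isinstance(e, Not):
            stack.append(e.child)
        elif isinstance(e, (And, Or)):
            stack.extend(e.children)
    return frozenset(out)


def substitute(expr: BoolExpr, mapping: Mapping[str, BoolExpr]) -> BoolExpr:
    """Replace each variable found in ``mapping`` by its expression (one layer)."""
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Var):
        return mapping.get(expr.name, expr)
    if isinstance(expr, Not):
        return Not(substitute(expr.child, mapping))
    if isinstance(expr, And):
        return And(tuple(substitute(c, mapping) for c in expr.children))
    if isinstance(expr, Or):
        return Or(tuple(substitute(c, mapping) for c in expr.children))
    raise TypeError(f"not a BoolExpr: {expr!r}")


def to_sympy(expr: BoolExpr, symbols: Mapping[str, sympy.Symbol] | None = None):
    """Convert to a sympy boolean expression (shared ``symbols`` recommended)."""
    if symbols is None:
        symbols = {}

    def sym(name: str) -> sympy.Symbol:
        if name not in symbols:
            symbols[name] = sympy.Symbol(name)  # type: ignore[index]
        return symbols[name]

    def rec(e: BoolExpr):
        if isinstance(e, Const):
            return sympy.true if e.value else sympy.false
        if isinstance(e, Var):
            return sym(e.name)
        if isinstance(e, Not):
            return _ba.Not(rec(e.child))
        if isinstance(e, And):
            return _ba.And(*(rec(c) for c in e.children))
        if isinstance(e, Or):
            return _ba.Or(*(rec(c) for c in e.children))
        raise TypeError(f"not a BoolExpr: {e!r}")

    return rec(expr)


def from_sympy(expr) -> BoolExpr:
    """Convert a sympy boolean expression back to a :class:`BoolExpr`.

    n-ary operands are sorted by their string form so the result is canonical
    regardless of sympy's internal argument ordering.
    """
    if expr is sympy.true or expr is True:
        return TRUE
    if expr is sympy.false or expr is False:
        return FALSE
    if isinstance(expr, sympy.Symbol):
        return Var(expr.name)
    if isinstance(expr, _ba.Not):
        return Not(from_sympy(expr.args[0]))
    if isinstance(expr, (_ba.And, _ba.Or)):
        kids = sorted((from_sympy(a) for a in expr.args), key=str)
        if len(kids) == 1:
            return kids[0]
        cls = And if isinstance(expr, _ba.And) else Or
        return cls(tuple(kids))
    raise TypeError(f"cannot convert sympy expression {expr!r}")


def _assignments(names: list[str]) -> Iterator[dict[str, int]]:
    for mask in range(1 << len(names)):
        yield {n: (mask >> i) & 1 for i, n in enumerate(names)}


def semantically_equal(a: BoolExpr, b: BoolExpr, max_vars: int = 16) -> bool:
    """Truth-table equality over the union of both expressions' variables."""
    names = sorted(variables(a) | variables(b))
    if len(names) > max_vars:
        raise ValueError(f"too many variables for truth-table check: {len(names)}")
    return all(evaluate(a, s) == evaluate(b, s) for s in _assignments(names))
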