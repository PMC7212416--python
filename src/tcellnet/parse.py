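"""Rule-text parsing and node-name normalization.

Two dialects are accepted, line by line:

* the internal dialect, ``name <- expr`` with ``and`` / ``or`` / ``not``,
  parentheses, constants ``0`` / ``1`` and the ``Input`` keyword;
* the BoolNet ``targets, factors`` dialect, ``name, expr`` with ``&``, ``|``,
  ``!`` (the word operators are accepted there too).

Node names appearing in the literature carry slashes, dashes and Greek letters
(CD80/86, CTLA-4dim, PKC0398;).  A fixed alias table plus a character-folding
fallback maps every spelling onto a canonical ASCII identifier, and name
resolution is case-insensitive, so ``Akt`` and ``AKT`` are the same node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .expr import And, BoolExpr, Const, Not, Or, Var

__all__ = [
    "ALIASES",
    "normalize_name",
    "parse_expr",
    "parse_rule_line",
    "parse_rules_text",
    "RuleParseError",
    "UndefinedNodeError",
    "DuplicateNodeError",
    "ParsedRule",
]

#: Canonical spellings for names whose raw form is not a bare identifier.
ALIASES: dict[str, str] = {
    "cd80/86": "CD8086",
    "cd80/86l": "CD8086",
    "cd8086": "CD8086",
    "ctla-4": "CTLA4",
    "ctla-4dim": "CTLA4dim",
    "ctla4dim": "CTLA4dim",
    "ctla-4dimers": "CTLA4dim",
    "pkcθ": "PKCT",
    "pkc-θ": "PKCT",
    "pkctheta": "PKCT",
    "pkct": "PKCT",
    "nf-κb": "NFKB",
    "nfκb": "NFKB",
    "nfkb": "NFKB",
    "rorγt": "RORGT",
    "rorgt": "RORGT",
    "rasgtpr": "RASGTPR",
    "rasgtp": "RASGTPR",
    "ndrg-1": "NDRG1",
    "ap-1": "AP1",
    "t-bet": "TBET",
    "ifnγ": "IFNG",
    "ifnγe": "IFNGE",
    "tgfβ": "TGFB",
    "tgfβe": "TGFBE",
    "il-2g": "IL2G",
}

_GREEK = str.maketrans({"θ": "T", "γ": "G", "κ": "K", "β": "B"})


def normalize_name(raw: str) -> str:
    """Canonical ASCII identifier for a raw node name."""
    key = raw.strip().lower()
    if key in ALIASES:
        return ALIASES[key]
    folded = raw.strip().translate(_GREEK)
    folded = re.sub(r"[-/. ]", "", folded)
    if folded.lower() in ALIASES:
        return ALIASES[folded.lower()]
    if not re.fullmatch(r"\w+", folded):
        raise RuleParseError(f"cannot normalize node name {raw!r}")
    return folded


class RuleParseError(ValueError):
    """Syntax error in rule text; carries line and column when known."""

    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {col}" if col is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.col = col


class UndefinedNodeError(RuleParseError):
    """A rule references a node that is never declared."""


class DuplicateNodeError(RuleParseError):
    """The same node is declared twice."""


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<amp>&+)|(?P<pipe>\|+)|(?P<bang>!)"
    r"|(?P<const>[01])(?![\w/])|(?P<name>[\wͰ-Ͽ][\wͰ-Ͽ/.-]*))"
)


def _tokenize(text: str, line_no: int | None) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise RuleParseError(
                f"unexpected character {text[pos]!r}", line_no, pos + 1
            )
        pos = m.end()
        kind = m.lastgroup
        val = m.group()
        if kind == "name":
            word = val.strip().lower()
            if word in ("and", "or", "not"):
                tokens.append((word, word, m.start()))
            elif word == "input":
                tokens.append(("input", word, m.start()))
            else:
                tokens.append(("name", val.strip(), m.start()))
        elif kind == "amp":
            tokens.append(("and", val, m.start()))
        elif kind == "pipe":
            tokens.append(("or", val, m.start()))
        elif kind == "bang":
            tokens.append(("not", val, m.start()))
        elif kind == "const":
            tokens.append(("const", val, m.start()))
        else:
            tokens.append((kind, val, m.start()))  # lpar / rpar
    return tokens


def parse_expr(text: str, line_no: int | None = None) -> BoolExpr:
    """Parse one Boolean expression (either operator style)."""
    tokens = _tokenize(text, line_no)
    if not tokens:
        raise RuleParseError("empty expression", line_no)
    pos = 0

    def peek() -> str | None:
        return tokens[pos][0] if pos < len(tokens) else None

    def take(kind: str) -> tuple[str, str, int]:
        nonlocal pos
        if pos >= len(tokens) or tokens[pos][0] != kind:
            got = tokens[pos][1] if pos < len(tokens) else "end of line"
            at = tokens[pos][2] + 1 if pos < len(tokens) else len(text)
            raise RuleParseError(f"expected {kind}, got {got!r}", line_no, at)
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> BoolExpr:
        terms = [parse_and()]
        while peek() == "or":
            take("or")
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> BoolExpr:
        factors = [parse_not()]
        while peek() == "and":
            take("and")
            factors.append(parse_not())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_not() -> BoolExpr:
        if peek() == "not":
            take("not")
            return Not(parse_not())
        return parse_atom()

    def parse_atom() -> BoolExpr:
        kind = peek()
        if kind == "lpar":
            take("lpar")
            e = parse_or()
            take("rpar")
            return e
        if kind == "const":
            return Const(int(take("const")[1]))
        if kind == "name":
            return Var(normalize_name(take("name")[1]))
        got = tokens[pos][1] if pos < len(tokens) else "end of line"
        at = tokens[pos][2] + 1 if pos < len(tokens) else len(text)
        raise RuleParseError(f"unexpected token {got!r}", line_no, at)

    expr = parse_or()
    if pos != len(tokens):
        raise RuleParseError(
            f"trailing input {tokens[pos][1]!r}", line_no, tokens[pos][2] + 1
        )
    return expr


@dataclass(frozen=True)
class ParsedRule:
    name: str
    expr: BoolExpr | None  # None marks an Input declaration
    line: int


def parse_rule_line(line: str, line_no: int | None = None) -> ParsedRule | None:
    """Parse one rule line of either dialect; returns None for blanks/comments."""
    stripped = line.strip()
    if not stripped or stripped.startswith("#"):
        return None
    if stripped.lower().replace(" ", "") in ("targets,factors", "targets,function"):
        return None  # BoolNet header
    if "<-" in stripped:
        lhs, rhs = stripped.split("<-", 1)
    elif "," in stripped:
        lhs, rhs = stripped.split(",", 1)
    else:
        raise RuleParseError(
            "expected 'name <- expr' or 'name, expr'", line_no, 1
        )
    name = normalize_name(lhs)
    rhs_stripped = rhs.strip()
    if rhs_stripped.lower() == "input":
        return ParsedRule(name, None, line_no or 0)
    expr = parse_expr(rhs, line_no)
    return ParsedRule(name, expr, line_no or 0)


def parse_rules_text(text: str) -> list[ParsedRule]:
    """Parse a whole rule file; raises on duplicates, defers undefined-name
    checking to the :class:`~tcellnet.network.Network` constructor."""
    if not text.strip():
        raise RuleParseError("empty rule text")
    rules: list[ParsedRule] = []
    seen: dict[str, int] = {}
    for i, line in enumerate(text.splitlines(), start=1):
        parsed = parse_rule_line(line, i)
        if parsed is None:
            continue
        if parsed.name in seen:
            raise DuplicateNodeError(
                f"node {parsed.name!r} already defined on line {seen[parsed.name]}",
                i,
            )
        seen[parsed.name] = i
        rules.append(parsed)
    if not rules:
        raise RuleParseError("no rules found")
    return rules
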