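"""Interop formats, run configuration and result serialization.

Networks round-trip through the BoolNet ``targets, factors`` dialect in a
normalized form: one rule per line in node order, ``&``/``|``/``!``
operators, single spaces, inputs written as self-identities.  Results are
written as TSV (matrices, trajectories) plus JSON (reports), with the run's
configuration and seed echoed into the output for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .basins import BasinReport
from .expr import And, BoolExpr, Const, Not, Or, Var
from .model import Attractor
from .network import Network, Trajectory, parse_rules
from .parse import RuleParseError

__all__ = [
    "read_bnet",
    "write_bnet",
    "format_bnet",
    "write_results",
    "RunConfig",
]


def read_bnet(path, hybrid: str | None = None) -> Network:
    """Read a BoolNet ``targets, factors`` file.

    Input nodes are detected as self-referential identities (``X, X``); a
    missing or malformed line raises a parse error carrying the line number.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        return parse_rules(text, hybrid=hybrid)
    except RuleParseError as err:
        raise RuleParseError(f"{path}: {err}") from err


def _fmt(expr: BoolExpr, parent: str | None = None) -> str:
    if isinstance(expr, Const):
        return str(expr.value)
    if isinstance(expr, Var):
        return expr.name
    if isinstance(expr, Not):
        inner = _fmt(expr.child, "not")
        return f"!{inner}"
    if isinstance(expr, And):
        s = " & ".join(_fmt(c, "and") for c in expr.children)
        return f"({s})" if parent in ("not", "or") else s
    if isinstance(expr, Or):
        s = " | ".join(_fmt(c, "or") for c in expr.children)
        return f"({s})" if parent in ("not", "and") else s
    raise TypeError(f"not a BoolExpr: {expr!r}")


def format_bnet(net: Network) -> str:
    """Normalized BoolNet text: node order preserved, operators canonical,
    whitespace canonicalized (term order is never reordered)."""
    lines = ["targets, factors"]
    for n in net.names:
        rule = net.rules[n]
        rhs = n if rule is None else _fmt(rule)
        lines.append(f"{n}, {rhs}")
    return "\n".join(lines) + "\n"


def write_bnet(net: Network, path) -> None:
    Path(path).write_text(format_bnet(net), encoding="utf-8")


@dataclass
class RunConfig:
    """Serializable description of a run; echoed into every output file."""

    model: str = "bundled"
    scheme: str = "sync"
    scenario: str | None = None
    beta: float = 50.0
    t_d: float = 10.0
    theta: float = 0.5
    clamps: dict = field(default_factory=dict)
    n_samples: int | None = None
    seed: int | None = None
    outdir: str = "results"
    verbosity: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in fields})


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def write_results(obj, outdir, config: RunConfig | None = None, prefix: str = "run"):
    """Write a basin report, attractor list or trajectory to ``outdir``.

    Basin reports become ``<prefix>_basins.{json,tsv}``; attractor lists
    ``<prefix>_attractors.{json,tsv}`` (nodes x attractors matrix); and
    trajectories ``<prefix>_trajectory.tsv`` (one row per step, step 0
    included).  Floats are written at fixed precision; the configuration and
    seed are embedded in every JSON payload.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {out}: {err}") from err
    meta = {"config": (config or RunConfig()).to_dict(), "schema_version": 1}
    written: list[Path] = []

    if isinstance(obj, BasinReport):
        payload = dict(meta)
        payload.update(
            {
                "method": obj.method,
                "n_total": obj.n_total,
                "seed": obj.seed,
                "cycle_count": obj.cycle_count,
                "fractions": {k: round(v, 6) for k, v in sorted(obj.fractions.items())},
                "stderr": {k: round(v, 6) for k, v in sorted(obj.stderr.items())},
                "class_counts": dict(sorted(obj.class_counts.items())),
            }
        )
        jp = out / f"{prefix}_basins.json"
        jp.write_text(json.dumps(payload, indent=2, default=_json_default))
        tp = out / f"{prefix}_basins.tsv"
        obj.summary().to_csv(tp, sep="\t", index=False, float_format="%.6f")
        written += [jp, tp]
    elif isinstance(obj, Trajectory):
        df = pd.DataFrame(obj.states)
        df.insert(0, "step", range(len(obj.states)))
        tp = out / f"{prefix}_trajectory.tsv"
        df.to_csv(tp, sep="\t", index=False)
        written.append(tp)
    elif isinstance(obj, Sequence) and obj and isinstance(obj[0], Attractor):
        from .basins import render_attractor_table

        tp = out / f"{prefix}_attractors.tsv"
        render_attractor_table(list(obj), path=tp)
        payload = dict(meta)
        payload["attractors"] = [
            {
                "label": a.label,
                "context": a.context_dict(),
                "scenario": a.scenario,
                "active_nodes": [n for n, v in a.state_dict().items() if v],
            }
            for a in obj
        ]
        jp = out / f"{prefix}_attractors.json"
        jp.write_text(json.dumps(payload, indent=2, default=_json_default))
        written += [tp, jp]
    else:
        raise TypeError(f"don't know how to write {type(obj)}")
    return written
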