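"""Basins of attraction: exhaustive and Monte-Carlo, with class aggregation.

The probability that a phenotypic pattern emerges is the relative basin size
p = omega / Omega, the fraction of initial states whose trajectory ends in an
attractor of that class.  Small networks are swept exhaustively; larger ones
are sampled uniformly at random (seeded), with binomial standard errors and a
stability check across two sample sizes.

Basin accounting here is synchronous-only by design: asynchronous basin sizes
depend on the arbitrary per-node update delays, so the asynchronous engine is
exposed elsewhere but carries no basin numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Attractor, CD4Model, build_model, classify
from .network import Network, SizeLimitError

__all__ = [
    "BasinReport",
    "basins_exhaustive",
    "basins_sampled",
    "core_trajectory_classifier",
    "render_attractor_table",
]

EXHAUSTIVE_BASIN_LIMIT = 24

#: classifier signature: (initial state dict, final state dict) -> label
Classifier = Callable[[Mapping[str, int], Mapping[str, int]], str]


@dataclass
class BasinReport:
    """Basin masses per attractor and per class.

    ``fractions`` are class-level p = omega/Omega; ``attractor_counts`` maps
    the attractor's state tuple to its basin count.  For sampled reports,
    ``stderr`` holds binomial standard errors and ``n_samples`` the sample
    size; for exhaustive reports the fractions are exact and sum to 1.
    """

    method: str
    n_total: int
    class_counts: dict[str, int]
    attractor_counts: dict[tuple[int, ...], int]
    cycle_count: int = 0
    seed: int | None = None
    names: tuple[str, ...] = ()

    @property
    def fractions(self) -> dict[str, float]:
        return {k: v / self.n_total for k, v in self.class_counts.items()}

    @property
    def stderr(self) -> dict[str, float]:
        out = {}
        for k, v in self.class_counts.items():
            p = v / self.n_total
            out[k] = math.sqrt(p * (1 - p) / self.n_total)
        return out

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "class": k,
                "count": v,
                "fraction": v / self.n_total,
                "stderr": self.stderr[k] if self.method.startswith("sampled") else 0.0,
            }
            for k, v in sorted(self.class_counts.items())
        ]
        return pd.DataFrame(rows)


def core_trajectory_classifier(model: CD4Model | None = None) -> Classifier:
    """Trajectory-level classifier for the activation core.

    Context is read off the initial state: the antigen context is the initial
    value of the latching TCR node, the costimulatory context is the CD8086
    input, and the anergy route is split by whether CD28 was initially
    engaged.
    """
    model = model or build_model()

    def _cls(init: Mapping[str, int], final: Mapping[str, int]) -> str:
        return classify(
            final,
            context={
                "TCR": init.get("TCR", 0),
                "CD8086": init.get("CD8086", 0),
            },
            model=model,
            mode="trajectory",
            cd28_initial=init.get("CD28", 0),
            check_fixed_point=False,
        )

    # only these initial bits influence the label: lets the tally aggregate
    # millions of samples into a handful of (context, attractor) groups
    _cls.init_keys = ("TCR", "CD8086", "CD28")
    return _cls


def _default_classifier(net: Network) -> Classifier:
    def _cls(init: Mapping[str, int], final: Mapping[str, int]) -> str:
        return "fixed_point"

    _cls.init_keys = ()
    return _cls


def _iterate_to_attractors(
    net: Network, states: np.ndarray, max_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate a batch synchronously; returns (final_states, converged_mask).

    States still changing after ``max_steps`` sweeps are cycle-trapped (or
    not yet converged); they are reported, not silently dropped.
    """
    step = net.compile_batch()
    cur = states
    active = np.ones(cur.shape[0], dtype=bool)
    for _ in range(max_steps):
        nxt = cur.copy()
        nxt[active] = step(cur[active])
        moved = (nxt != cur).any(axis=1)
        cur = nxt
        active &= moved
        if not active.any():
            break
    final_fixed = (step(cur) == cur).all(axis=1)
    return cur, final_fixed


def _tally(
    net: Network,
    inits: np.ndarray,
    finals: np.ndarray,
    fixed_mask: np.ndarray,
    classifier: Classifier,
) -> tuple[dict, dict, int]:
    class_counts: dict[str, int] = {}
    att_counts: dict[tuple[int, ...], int] = {}
    names = net.names
    n_cycle = int((~fixed_mask).sum())
    # Group rows on (classification-relevant initial bits, final state): the
    # classifier then runs once per group, not once per sample.
    init_keys = tuple(getattr(classifier, "init_keys", names))
    key_idx = [names.index(k) for k in init_keys]
    both = np.concatenate(
        [inits[fixed_mask][:, key_idx], finals[fixed_mask]], axis=1
    )
    uniq, counts = np.unique(both, axis=0, return_counts=True)
    k = len(key_idx)
    for row, c in zip(uniq, counts):
        init_d = dict(zip(init_keys, (int(b) for b in row[:k])))
        final_bits = tuple(int(b) for b in row[k:])
        final_d = dict(zip(names, final_bits))
        label = classifier(init_d, final_d)
        class_counts[label] = class_counts.get(label, 0) + int(c)
        att_counts[final_bits] = att_counts.get(final_bits, 0) + int(c)
    return class_counts, att_counts, n_cycle


def basins_exhaustive(
    net: Network,
    classifier: Classifier | None = None,
    max_steps: int | None = None,
    chunk_bits: int = 18,
) -> BasinReport:
    """Exact basins by sweeping every initial state (bounded at 24 nodes)."""
    n = net.n_nodes
    if n > EXHAUSTIVE_BASIN_LIMIT:
        raise SizeLimitError(
            f"{n} nodes exceeds the exhaustive basin bound of "
            f"{EXHAUSTIVE_BASIN_LIMIT}; use basins_sampled or a reduced network"
        )
    classifier = classifier or _default_classifier(net)
    max_steps = max_steps or 4 * n
    total = 1 << n
    class_counts: dict[str, int] = {}
    att_counts: dict[tuple[int, ...], int] = {}
    n_cycle = 0
    for start in range(0, total, 1 << chunk_bits):
        codes = np.arange(start, min(start + (1 << chunk_bits), total), dtype=np.uint64)
        states = ((codes[:, None] >> np.arange(n, dtype=np.uint64)) & 1).astype(bool)
        finals, fixed = _iterate_to_attractors(net, states, max_steps)
        cc, ac, nc = _tally(net, states, finals, fixed, classifier)
        for k, v in cc.items():
            class_counts[k] = class_counts.get(k, 0) + v
        for k, v in ac.items():
            att_counts[k] = att_counts.get(k, 0) + v
        n_cycle += nc
    return BasinReport(
        method="exhaustive",
        n_total=total,
        class_counts=class_counts,
        attractor_counts=att_counts,
        cycle_count=n_cycle,
        names=net.names,
    )


def basins_sampled(
    net: Network,
    n_samples: int,
    seed: int | None = None,
    classifier: Classifier | None = None,
    max_steps: int | None = None,
    chunk: int = 1 << 18,
) -> BasinReport:
    """Monte-Carlo basins from uniform random initial states (seeded)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    classifier = classifier or _default_classifier(net)
    max_steps = max_steps or 4 * net.n_nodes
    rng = np.random.default_rng(seed)
    class_counts: dict[str, int] = {}
    att_counts: dict[tuple[int, ...], int] = {}
    n_cycle = 0
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        states = rng.integers(0, 2, size=(m, net.n_nodes), dtype=np.int8).astype(bool)
        finals, fixed = _iterate_to_attractors(net, states, max_steps)
        cc, ac, nc = _tally(net, states, finals, fixed, classifier)
        for k, v in cc.items():
            class_counts[k] = class_counts.get(k, 0) + v
        for k, v in ac.items():
            att_counts[k] = att_counts.get(k, 0) + v
        n_cycle += nc
    return BasinReport(
        method=f"sampled(n={n_samples})",
        n_total=n_samples,
        class_counts=class_counts,
        attractor_counts=att_counts,
        cycle_count=n_cycle,
        seed=seed,
        names=net.names,
    )


def render_attractor_table(
    attractors: Sequence[Attractor],
    ordering: Sequence[str] | None = None,
    path=None,
) -> pd.DataFrame:
    """Nodes x attractors 0/1 matrix with class labels, optionally as TSV.

    Column order follows the given class ``ordering`` (default: the order the
    attractors come in); rows are the node names of the first attractor.
    """
    if not attractors:
        raise ValueError("no attractors to render")
    atts = list(attractors)
    if ordering is not None:
        rank = {label: i for i, label in enumerate(ordering)}
        atts.sort(key=lambda a: (rank.get(a.label, len(rank)), a.context, a.state))
    names = atts[0].names
    data = {}
    for i, a in enumerate(atts):
        data[f"{a.label}#{i}"] = list(a.state)
    df = pd.DataFrame(data, index=list(names))
    if path is not None:
        df.to_csv(path, sep="\t")
    return df
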