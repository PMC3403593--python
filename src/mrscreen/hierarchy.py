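"""Regulatory-hierarchy placement of candidate TFs by breadth-first levels.

A merged TF->gene network is layered by shortest directed distance from
its root set: roots are the zero-in-degree nodes (if none exists — the
graph may be cyclic — all nodes of minimal in-degree, logged).  Master
regulators are expected near the top of this layering, downstream effector
genes near the bottom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .iodata import canon

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HierarchyLevels:
    levels: Mapping[str, int]  # canonical node -> BFS level
    roots: frozenset[str]
    unreachable: frozenset[str]
    display: Mapping[str, str]

    @property
    def n_levels(self) -> int:
        return (max(self.levels.values()) + 1) if self.levels else 0


def bfs_levels(edges: Iterable[tuple[str, str]]) -> HierarchyLevels:
    """Layer a directed network by shortest distance from its roots.

    Cycles are permitted.  Nodes unreachable from the root set are flagged
    rather than placed.
    """
    g = nx.DiGraph()
    display: dict[str, str] = {}
    for a, b in sorted(edges):
        ca, cb = canon(a), canon(b)
        display.setdefault(ca, a)
        display.setdefault(cb, b)
        g.add_edge(ca, cb)
    if g.number_of_nodes() == 0:
        return HierarchyLevels(
            levels={}, roots=frozenset(), unreachable=frozenset(), display={}
        )
    roots = {n for n, d in g.in_degree() if d == 0}
    if not roots:
        min_in = min(d for _, d in g.in_degree())
        roots = {n for n, d in g.in_degree() if d == min_in}
        log.info(
            "no zero-in-degree node; using %d nodes of minimal in-degree %d "
            "as roots", len(roots), min_in,
        )
    levels = nx.multi_source_dijkstra_path_length(g, roots, weight=None)
    levels = {n: int(l) for n, l in levels.items()}
    unreachable = frozenset(set(g.nodes) - set(levels))
    if unreachable:
        log.info("%d nodes unreachable from the root set", len(unreachable))
    return HierarchyLevels(
        levels=levels,
        roots=frozenset(roots),
        unreachable=unreachable,
        display=display,
    )


def _band(level: int, n_levels: int) -> str:
    """top / middle / bottom thirds by level rank."""
    if n_levels <= 1:
        return "top"
    frac = level / (n_levels - 1)
    if frac <= 1 / 3:
        return "top"
    if frac <= 2 / 3:
        return "middle"
    return "bottom"


def locate_candidates(
    levels: HierarchyLevels, tf_set: Iterable[str]
) -> pd.DataFrame:
    """Per-TF level and top/middle/bottom band; absent TFs reported as such."""
    n_levels = levels.n_levels
    rows = []
    for tf in sorted(set(tf_set), key=canon):
        c = canon(tf)
        if c in levels.levels:
            lv = levels.levels[c]
            rows.append(
                {"tf": tf, "level": lv, "band": _band(lv, n_levels),
                 "status": "placed"}
            )
        elif c in levels.unreachable:
            rows.append(
                {"tf": tf, "level": pd.NA, "band": pd.NA,
                 "status": "unreachable"}
            )
        else:
            rows.append(
                {"tf": tf, "level": pd.NA, "band": pd.NA, "status": "absent"}
            )
    return pd.DataFrame(rows, columns=["tf", "level", "band", "status"])
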