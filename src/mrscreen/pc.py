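"""Skeleton inference by a modified path-consistency (PC) algorithm.

Starting from the complete undirected graph, edges are tested for removal
with partial correlations of increasing order (conditioning-set size).  An
edge is removed as soon as some conditioning set renders the pair
conditionally independent; the set is recorded as the pair's separating
set.  The algorithm stops naturally once no edge has enough adjacent
variables left to form a conditioning set of the current order.

The modification for expression data: microarray profiles are frequently
near-duplicated, and the induced multicollinearity makes some partial
correlations numerically unevaluable.  Instead of aborting, any pair whose
test is violated at any order is regarded as *dependent* — the edge is kept
without a statistical test and flagged ``kept-multicollinear`` — which
guarantees natural termination on data containing perfectly correlated
genes.

Two modes are provided.  In sample-data mode the correlation matrix is
estimated from one cell's samples and conditional independence is judged by
the Fisher z test at a configurable alpha.  In oracle-covariance mode a
population correlation matrix is supplied directly and independence means a
partial correlation within ``zero_tol`` of zero — useful for worked
examples with known structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy import stats

from .iodata import CELLS, Cell, ExpressionDataset, canon

log = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class PCConfig:
    """Tuning knobs for :func:`modified_pc`.

    alpha       significance level of the Fisher z independence test
    max_order   cap on conditioning-set size (None = natural stop only)
    mode        'sample-data' or 'oracle-covariance'
    zero_tol    |partial correlation| below this counts as zero (oracle mode)
    cond_limit  condition number above which a test is declared violated
    """

    alpha: float = 0.05
    max_order: int | None = None
    mode: Literal["sample-data", "oracle-covariance"] = "sample-data"
    zero_tol: float = 1e-8
    cond_limit: float = 1e10

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.zero_tol <= 0:
            raise ValueError("zero_tol must be positive")


@dataclass(frozen=True)
class RemovalRecord:
    pair: Pair
    order: int
    sepset: tuple[str, ...]
    statistic: float
    p: float


@dataclass
class Skeleton:
    """Undirected inferred graph with a full edge-removal audit log."""

    nodes: tuple[str, ...]
    edges: set[Pair]
    removal_log: list[RemovalRecord] = field(default_factory=list)
    retained_flags: set[Pair] = field(default_factory=set)
    skipped_tests: list[str] = field(default_factory=list)
    dropped_constant: tuple[str, ...] = ()

    def has_edge(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.edges


def partial_corr(
    corr: np.ndarray,
    i: int,
    j: int,
    S: Iterable[int],
    cond_limit: float = 1e10,
) -> tuple[float, bool]:
    """Partial correlation of variables i and j given the set S.

    Computed by inverting the sub-correlation matrix on {i, j} | S: with
    K the inverse, r = -K_ij / sqrt(K_ii K_jj).  Returns ``(r, ok)`` where
    ``ok`` is False when the submatrix is singular or ill-conditioned
    (condition number beyond ``cond_limit``), or the result is non-finite
    or has modulus >= 1 - 1e-12.  Failure is a returned state, never an
    exception — the retained-edge modification depends on it.
    """
    S = list(S)
    idx = [i, j] + S
    sub = np.asarray(corr, dtype=float)[np.ix_(idx, idx)]
    try:
        if np.linalg.cond(sub) > cond_limit:
            return 0.0, False
        K = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        return 0.0, False
    denom = K[0, 0] * K[1, 1]
    if denom <= 0:
        return 0.0, False
    r = float(-K[0, 1] / np.sqrt(denom))
    if not np.isfinite(r) or abs(r) >= 1.0 - 1e-12:
        return r, False
    return r, True


def fisher_z_test(
    r: float, n: int, order: int, alpha: float
) -> tuple[float, bool]:
    """Fisher z test of a partial correlation of the given order.

    z = atanh(r); the statistic sqrt(n - order - 3) * |z| is compared with
    the standard normal: p = 2 * (1 - Phi(.)).  Requires n - order - 3 >= 1;
    callers must skip the test otherwise.  Returns (p, independent) with
    independent <=> p > alpha.
    """
    df = n - order - 3
    if df < 1:
        raise ValueError("insufficient samples for Fisher z test")
    z = 0.5 * np.log((1.0 + r) / (1.0 - r))
    p = float(2.0 * stats.norm.sf(np.sqrt(df) * abs(z)))
    return p, p > alpha


def _independent(
    r: float,
    n: int | None,
    order: int,
    config: PCConfig,
) -> tuple[float, float, bool]:
    """(statistic, p, independent) under the configured mode."""
    if config.mode == "oracle-covariance":
        return r, float("nan"), abs(r) < config.zero_tol
    p, indep = fisher_z_test(r, n, order, config.alpha)
    return r, p, indep


def modified_pc(
    dataset: ExpressionDataset | None = None,
    *,
    corr: np.ndarray | None = None,
    var_names: tuple[str, ...] | None = None,
    n_samples: int | None = None,
    config: PCConfig | None = None,
) -> Skeleton:
    """Infer an undirected skeleton with the retained-edge modification.

    Either an :class:`ExpressionDataset` (one cell's samples; sample-data
    mode) or a correlation matrix with variable names (oracle mode, or
    sample mode with explicit ``n_samples``) must be supplied.  Variables
    are processed in lexicographic symbol order, edges in lexicographic
    pair order, and conditioning subsets in lexicographic order from the
    adjacency of each endpoint in turn, with the adjacency structure
    updated immediately after every removal (classic PC scheduling, no
    order permutation).  A numerical failure at any subset keeps the edge,
    flags it ``kept-multicollinear``, and ends testing of that edge for the
    current order; the edge is re-eligible at higher orders.
    """
    config = config or PCConfig()
    dropped_constant: tuple[str, ...] = ()
    if dataset is not None:
        order_names = sorted(dataset.gene_ids, key=canon)
        values = np.array(
            [dataset.values[dataset.gene_row(g)] for g in order_names]
        )
        n = values.shape[1]
        if n >= 2:
            keep = values.std(axis=1) > 0
        else:
            # a single sample gives no variance information; keep everything
            keep = np.ones(len(order_names), dtype=bool)
        dropped_constant = tuple(
            g for g, k in zip(order_names, keep) if not k
        )
        if dropped_constant:
            log.info(
                "dropped %d constant genes before PC: %s",
                len(dropped_constant), list(dropped_constant)[:5],
            )
        names = tuple(g for g, k in zip(order_names, keep) if k)
        values = values[keep]
        if len(names) < 2:
            raise ValueError("need at least 2 non-constant variables")
        if n >= 2:
            corr_mat = np.corrcoef(values)
        else:
            corr_mat = np.eye(len(names))
    else:
        if corr is None or var_names is None:
            raise ValueError("supply a dataset, or corr with var_names")
        perm = sorted(range(len(var_names)), key=lambda k: canon(var_names[k]))
        names = tuple(var_names[k] for k in perm)
        corr_mat = np.asarray(corr, dtype=float)[np.ix_(perm, perm)]
        n = n_samples

    p = len(names)
    index = {nm: k for k, nm in enumerate(names)}
    adj: dict[str, set[str]] = {nm: set(names) - {nm} for nm in names}
    edges: set[Pair] = {
        (a, b) for a, b in combinations(names, 2)
    }
    sk = Skeleton(nodes=names, edges=edges, dropped_constant=dropped_constant)

    if config.mode == "sample-data" and (n is None or n - 3 < 1):
        # no zeroth-order test is possible; every edge stays untested
        sk.skipped_tests.append(
            f"all tests skipped: {n} samples are too few for the Fisher z "
            f"test; complete graph returned"
        )
        log.warning(sk.skipped_tests[-1])
        return sk

    def test_edge(a: str, b: str, order: int) -> bool:
        """Try to remove edge (a, b) at this order.  True if removed."""
        seen: set[tuple[str, ...]] = set()
        for anchor, other in ((a, b), (b, a)):
            neighbours = sorted(adj[anchor] - {other})
            if len(neighbours) < order:
                continue
            for S in combinations(neighbours, order):
                if S in seen:
                    continue
                seen.add(S)
                if config.mode == "sample-data" and n - order - 3 < 1:
                    sk.skipped_tests.append(
                        f"({a},{b}) order {order}: n={n} too small; edge kept"
                    )
                    return False
                r, ok = partial_corr(
                    corr_mat, index[a], index[b],
                    [index[s] for s in S], config.cond_limit,
                )
                if not ok:
                    sk.retained_flags.add((a, b))
                    log.debug(
                        "edge (%s,%s) kept-multicollinear at order %d "
                        "(S=%s)", a, b, order, S,
                    )
                    return False
                stat, pval, indep = _independent(r, n, order, config)
                if indep:
                    sk.edges.discard((a, b))
                    sk.retained_flags.discard((a, b))
                    adj[a].discard(b)
                    adj[b].discard(a)
                    sk.removal_log.append(
                        RemovalRecord(
                            pair=(a, b), order=order, sepset=S,
                            statistic=stat, p=pval,
                        )
                    )
                    return True
        return False

    order = 0
    while True:
        if config.max_order is not None and order > config.max_order:
            break
        eligible = any(
            len(adj[x] - {y}) >= order
            for (a, b) in sk.edges
            for (x, y) in ((a, b), (b, a))
        )
        if not eligible:
            break
        for a, b in sorted(sk.edges):
            if (a, b) not in sk.edges:
                continue
            test_edge(a, b, order)
        order += 1

    return sk


def infer_cells(
    dataset: ExpressionDataset, config: PCConfig | None = None
) -> dict[Cell, Skeleton]:
    """One skeleton per strain-by-period cell (deterministic; PC has no RNG)."""
    return {
        (strain, period): modified_pc(
            dataset.cell(strain, period), config=config
        )
        for strain, period in CELLS
    }
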