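"""Network screening: Gaussian-network likelihood and graph consistency probability.

A reference network is scored against expression data by the log-likelihood
of a linear Gaussian network without intercepts: each node is regressed on
its graph parents by ordinary least squares and contributes

    -(m/2) * (1 + ln(2 pi sigma_i^2))

to the total, where ``sigma_i^2`` is the maximum-likelihood residual
variance (denominator ``m``, the number of samples) and a parentless node's
fit is the zero function.  Because the model has no intercept, every gene
is standardized (zero mean, unit variance, denominator ``m``) within the
scored strain-by-period cell before fitting.

The likelihood depends on graph size, so it is converted into an empirical
probability: ``N_r`` random DAGs with the same node and edge counts are
scored on the same data, and the graph consistency probability (GCP) is the
fraction of random graphs scoring *strictly higher*.  A small GCP means few
random structures fit the data better than the tested structure; a network
is flagged active when GCP falls below ``alpha`` (default 0.05, with
``N_r`` defaulting to 2000).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .iodata import CELLS, Cell, ExpressionDataset, RegulatoryNetwork, canon

log = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)
#: residual variances at or below this are treated as degenerate (exact fit)
SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class NodeFit:
    node: str
    n_parents: int
    sigma2: float
    betas: np.ndarray
    contribution: float  # NaN when degenerate
    degenerate: bool = False
    underdetermined: bool = False


@dataclass(frozen=True)
class LikelihoodResult:
    network_id: str
    total_loglik: float
    per_node: tuple[NodeFit, ...]
    dropped_nodes: tuple[str, ...] = ()
    sentinel_nodes: tuple[str, ...] = ()

    @property
    def n_scored_nodes(self) -> int:
        return len(self.per_node) - len(self.sentinel_nodes)


@dataclass(frozen=True)
class GCPResult:
    network_id: str
    observed_loglik: float
    n_random: int
    n_better: int
    gcp: float
    significant: bool
    seed: int

    def __post_init__(self) -> None:
        assert 0 <= self.n_better <= self.n_random
        assert self.gcp == self.n_better / self.n_random


def standardize(values: np.ndarray) -> np.ndarray:
    """Per-row zero-mean unit-variance scaling with ML denominator m.

    Rows with zero variance are centred only (their variance is degenerate
    either way and is caught downstream by the sigma^2 sentinel).
    """
    x = np.asarray(values, dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = np.sqrt(np.mean((x - mu) ** 2, axis=1, keepdims=True))
    sd = np.where(sd <= 0, 1.0, sd)
    return (x - mu) / sd


def node_loglik(
    child_values: np.ndarray, parent_matrix: np.ndarray | None = None,
    node: str = "",
) -> NodeFit:
    """Single-node Gaussian log-likelihood contribution.

    ``child_values`` has length m; ``parent_matrix`` is m x n_i (one column
    per parent) or None for a parentless node, whose fit is the zero
    function so that sigma^2 is the mean of squares.  Betas are no-intercept
    least squares; an underdetermined system (n_i >= m) is solved by
    pseudoinverse and flagged.  sigma^2 = RSS/m; a (near-)zero sigma^2
    marks the node degenerate and its contribution is NaN — callers exclude
    such nodes from likelihood comparisons.
    """
    x = np.asarray(child_values, dtype=float)
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples per node")
    if parent_matrix is None or parent_matrix.size == 0:
        betas = np.zeros(0)
        resid = x
        underdetermined = False
    else:
        P = np.asarray(parent_matrix, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        betas, *_ = np.linalg.lstsq(P, x, rcond=None)
        resid = x - P @ betas
        underdetermined = P.shape[1] >= m
    sigma2 = float(np.mean(resid**2))
    degenerate = sigma2 <= SIGMA2_FLOOR
    contribution = (
        math.nan if degenerate else -(m / 2.0) * (1.0 + LOG_2PI + math.log(sigma2))
    )
    return NodeFit(
        node=node,
        n_parents=int(betas.shape[0]),
        sigma2=sigma2,
        betas=betas,
        contribution=contribution,
        degenerate=degenerate,
        underdetermined=underdetermined,
    )


def _network_nodes_and_parents(
    network: RegulatoryNetwork, dataset: ExpressionDataset
) -> tuple[list[str], dict[str, list[str]], list[str]]:
    """Present nodes (canonical), their parent lists, and dropped symbols."""
    node_display: dict[str, str] = {}
    for tf, tg in sorted(network.edges):
        node_display.setdefault(canon(tf), tf)
        node_display.setdefault(canon(tg), tg)
    present = [c for c in sorted(node_display) if dataset.gene_row(c) is not None]
    dropped = [node_display[c] for c in sorted(node_display) if c not in present]
    present_set = set(present)
    parents: dict[str, list[str]] = {c: [] for c in present}
    for tf, tg in sorted(network.edges):
        ctf, ctg = canon(tf), canon(tg)
        if ctf in present_set and ctg in present_set:
            parents[ctg].append(ctf)
    return present, parents, dropped


def network_loglik(
    network: RegulatoryNetwork, dataset: ExpressionDataset
) -> LikelihoodResult | None:
    """Score a whole network on one cell's data (Gaussian-network likelihood).

    Nodes absent from the expression data are dropped together with their
    incident edges (logged).  Returns None (skip, with a warning) when
    fewer than 2 network nodes remain.  The dataset is standardized per
    gene internally.
    """
    present, parents, dropped = _network_nodes_and_parents(network, dataset)
    if dropped:
        log.info(
            "network %s: dropped %d nodes absent from data",
            network.network_id, len(dropped),
        )
    if len(present) < 2:
        log.warning(
            "network %s reduced to <2 nodes; skipped", network.network_id
        )
        return None
    rows = np.array([dataset.gene_row(c) for c in present])
    X = standardize(dataset.values[rows, :])
    row_of = {c: i for i, c in enumerate(present)}

    fits = []
    sentinels = []
    total = 0.0
    for c in present:
        pidx = [row_of[p] for p in parents[c]]
        P = X[pidx, :].T if pidx else None
        fit = node_loglik(X[row_of[c], :], P, node=c)
        fits.append(fit)
        if fit.degenerate:
            sentinels.append(c)
            log.info(
                "network %s: node %s has sigma^2=0 (exact fit); excluded "
                "from likelihood comparison", network.network_id, c,
            )
        else:
            total += fit.contribution
        if fit.underdetermined:
            log.info(
                "network %s: node %s underdetermined (%d parents, m=%d)",
                network.network_id, c, fit.n_parents, X.shape[1],
            )
    return LikelihoodResult(
        network_id=network.network_id,
        total_loglik=total,
        per_node=tuple(fits),
        dropped_nodes=tuple(dropped),
        sentinel_nodes=tuple(sentinels),
    )


def random_dag(
    n_nodes: int, n_edges: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Draw a random DAG on ``n_nodes`` labelled nodes with exactly ``n_edges``.

    A topological order is drawn uniformly, then ``n_edges`` distinct
    forward (order-respecting) pairs are drawn uniformly, so the result is
    acyclic by construction.  Edges are (parent, child) index pairs.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(
            f"n_edges={n_edges} outside [0, {max_edges}] for {n_nodes} nodes"
        )
    order = rng.permutation(n_nodes)
    rows, cols = np.triu_indices(n_nodes, k=1)
    chosen = rng.choice(max_edges, size=n_edges, replace=False) if n_edges else []
    return [(int(order[rows[k]]), int(order[cols[k]])) for k in chosen]


def _fast_total_loglik(
    S: np.ndarray,
    m: int,
    edges: Sequence[tuple[int, int]],
    n_nodes: int,
    excluded: frozenset[int],
) -> float:
    """Total likelihood of an edge set via the covariance matrix.

    For standardized data the no-intercept OLS residual variance of node i
    with parent set P is  S_ii - S_iP S_PP^{-1} S_Pi,  which avoids
    re-touching the raw samples for every random draw.  Exact-fit variances
    are clamped at the sigma^2 floor.
    """
    parents: list[list[int]] = [[] for _ in range(n_nodes)]
    for a, b in edges:
        parents[b].append(a)
    total = 0.0
    for i in range(n_nodes):
        if i in excluded:
            continue
        p = parents[i]
        if not p:
            sigma2 = S[i, i]
        else:
            Spp = S[np.ix_(p, p)]
            Spi = S[p, i]
            try:
                coef = np.linalg.solve(Spp, Spi)
            except np.linalg.LinAlgError:
                coef = np.linalg.pinv(Spp) @ Spi
            sigma2 = S[i, i] - float(Spi @ coef)
        sigma2 = max(sigma2, SIGMA2_FLOOR)
        total += -(m / 2.0) * (1.0 + LOG_2PI + math.log(sigma2))
    return total


def gcp(
    network: RegulatoryNetwork,
    dataset: ExpressionDataset,
    n_random: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> GCPResult | None:
    """Graph consistency probability of one network on one cell's data.

    ``N_r`` random DAGs with the network's node and edge counts are scored
    on the same (standardized) data; ``N_s`` counts those with *strictly*
    larger log-likelihood (ties are not counted) and GCP = N_s / N_r.
    Degenerate (sigma^2 = 0) nodes of the observed fit are excluded from
    both the observed and every random total, so both sides sum over the
    same node set.  The same seed reproduces the result bit-exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    used_seed = -1 if seed is None else int(seed)

    observed = network_loglik(network, dataset)
    if observed is None:
        return None
    present, _parents, _dropped = _network_nodes_and_parents(network, dataset)
    rows = np.array([dataset.gene_row(c) for c in present])
    X = standardize(dataset.values[rows, :])
    m = X.shape[1]
    S = (X @ X.T) / m
    n_nodes = len(present)
    n_edges = sum(
        1
        for tf, tg in {(canon(a), canon(b)) for a, b in network.edges}
        if tf in set(present) and tg in set(present)
    )
    excluded = frozenset(
        present.index(c) for c in observed.sentinel_nodes
    )

    n_better = 0
    for _ in range(n_random):
        edges = random_dag(n_nodes, n_edges, rng)
        total = _fast_total_loglik(S, m, edges, n_nodes, excluded)
        if total > observed.total_loglik:
            n_better += 1
    value = n_better / n_random
    return GCPResult(
        network_id=network.network_id,
        observed_loglik=observed.total_loglik,
        n_random=n_random,
        n_better=n_better,
        gcp=value,
        significant=value < alpha,
        seed=used_seed,
    )


def screen_collection(
    collection: Sequence[RegulatoryNetwork],
    dataset: ExpressionDataset,
    n_random: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[Cell, list[GCPResult]]:
    """Screen every network in every strain-by-period cell.

    Child seeds derive from the master seed by a documented counter scheme:
    the RNG for network ``j`` in cell ``i`` (cells in canonical order) is
    ``np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, j)))``,
    so serial and parallel execution agree and results are reproducible
    bit-exactly.
    """
    results: dict[Cell, list[GCPResult]] = {}
    for ci, (strain, period) in enumerate(CELLS):
        cell_data = dataset.cell(strain, period)
        cell_results = []
        for nj, network in enumerate(collection):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(ci, nj))
            )
            res = gcp(
                network, cell_data, n_random=n_random, alpha=alpha,
                rng=rng, seed=seed,
            )
            if res is not None:
                cell_results.append(res)
        results[(strain, period)] = cell_results
    return results


def active_networks(
    collection: Sequence[RegulatoryNetwork],
    screen_results: Mapping[Cell, Sequence[GCPResult]],
) -> dict[Cell, list[RegulatoryNetwork]]:
    """Networks flagged significant (GCP < alpha) per cell."""
    by_id = {n.network_id: n for n in collection}
    return {
        cell: [by_id[r.network_id] for r in results if r.significant]
        for cell, results in screen_results.items()
    }
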