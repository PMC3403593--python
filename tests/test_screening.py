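"""Gaussian-network likelihood and GCP: oracles, properties, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from mrscreen.iodata import RegulatoryNetwork
from mrscreen.screening import (
    gcp,
    network_loglik,
    node_loglik,
    random_dag,
    screen_collection,
    standardize,
)

from conftest import make_dataset, make_six_cell_dataset


# -- independent oracle: term-by-term Gaussian log-density on OLS residuals --


def oracle_node_loglik(child, parents):
    """Normal-equation OLS + per-sample normal log-density (ML sigma^2)."""
    child = np.asarray(child, dtype=float)
    if parents is None or parents.size == 0:
        pred = np.zeros_like(child)
    else:
        P = np.asarray(parents, dtype=float)
        beta = np.linalg.pinv(P.T @ P) @ (P.T @ child)
        pred = P @ beta
    sigma2 = np.mean((child - pred) ** 2)
    return float(
        np.sum(stats.norm.logpdf(child, loc=pred, scale=math.sqrt(sigma2)))
    ), sigma2


def oracle_network_loglik(parent_map, data_rows):
    total = 0.0
    for node, parents in parent_map.items():
        P = (
            np.column_stack([data_rows[p] for p in parents])
            if parents
            else None
        )
        contrib, _ = oracle_node_loglik(data_rows[node], P)
        total += contrib
    return total


class TestNodeLoglik:
    def test_parentless_unit_variance(self):
        fit = node_loglik(np.array([1.0, -1.0]))
        assert fit.sigma2 == pytest.approx(1.0)
        assert fit.contribution == pytest.approx(-(1 + math.log(2 * math.pi)))

    def test_exact_parent_copy_is_degenerate(self):
        x = np.array([0.3, -1.2, 0.5, 1.1])
        fit = node_loglik(x, x[:, None])
        assert fit.degenerate and math.isnan(fit.contribution)

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(20):
            child = rng.normal(size=20)
            parents = rng.normal(size=(20, 2))
            fit = node_loglik(child, parents)
            expected, sigma2 = oracle_node_loglik(child, parents)
            assert fit.contribution == pytest.approx(expected, rel=1e-12)
            assert fit.sigma2 == pytest.approx(sigma2, rel=1e-12)

    def test_monotone_in_parent_set(self, rng):
        # OLS nesting: adding a parent never decreases the contribution
        for _ in range(20):
            child = rng.normal(size=15)
            parents = rng.normal(size=(15, 3))
            small = node_loglik(child, parents[:, :2]).contribution
            big = node_loglik(child, parents).contribution
            assert big >= small - 1e-9


class TestNetworkLoglik:
    def test_empty_edge_network_is_sum_of_parentless(self, rng):
        # a network must have edges, so compare a chain against manual sums
        data = rng.normal(size=(3, 12))
        ds = make_dataset(data, genes=["A", "B", "C"])
        net = RegulatoryNetwork("n", "n", frozenset({("A", "B"), ("B", "C")}))
        res = network_loglik(net, ds)
        X = standardize(data)
        rows = {"a": X[0], "b": X[1], "c": X[2]}
        expected = oracle_network_loglik(
            {"a": [], "b": ["a"], "c": ["b"]}, rows
        )
        assert res.total_loglik == pytest.approx(expected, rel=1e-9)

    def test_oracle_equivalence_random_dags(self, rng):
        """Whole-network score equals an independent brute-force evaluation."""
        for trial in range(100):
            n_nodes = 6
            genes = [f"g{i}" for i in range(n_nodes)]
            edges = random_dag(n_nodes, int(rng.integers(0, 10)), rng)
            if not edges:
                continue
            net = RegulatoryNetwork(
                "r", "r", frozenset({(genes[a], genes[b]) for a, b in edges})
            )
            data = rng.normal(size=(n_nodes, 15))
            ds = make_dataset(data, genes=genes)
            res = network_loglik(net, ds)
            X = standardize(data)
            node_set = sorted({g for e in net.edges for g in e})
            parent_map = {g: [] for g in node_set}
            for a, b in net.edges:
                parent_map[b].append(a)
            rows = {g: X[genes.index(g)] for g in node_set}
            expected = oracle_network_loglik(parent_map, rows)
            assert res.total_loglik == pytest.approx(expected, rel=1e-9)

    def test_missing_node_dropped(self, rng):
        ds = make_dataset(rng.normal(size=(2, 10)), genes=["A", "B"])
        net = RegulatoryNetwork(
            "n", "n", frozenset({("A", "B"), ("A", "Zmissing")})
        )
        res = network_loglik(net, ds)
        assert res.dropped_nodes == ("Zmissing",)
        assert len(res.per_node) == 2

    def test_noiseless_chain_hits_sentinels(self):
        base = np.array([1.0, -2.0, 0.5, 3.0, -1.5])
        data = np.vstack([base, base * 2.0, base * -1.0])
        ds = make_dataset(data, genes=["A", "B", "C"])
        net = RegulatoryNetwork("n", "n", frozenset({("A", "B"), ("B", "C")}))
        res = network_loglik(net, ds)
        assert set(res.sentinel_nodes) == {"b", "c"}


class TestRandomDag:
    def test_zero_edges(self, rng):
        assert random_dag(5, 0, rng) == []

    def test_too_many_edges_rejected(self, rng):
        with pytest.raises(ValueError):
            random_dag(4, 7, rng)

    def test_always_acyclic_with_exact_count(self, rng):
        import networkx as nx

        for _ in range(2000):
            edges = random_dag(4, 3, rng)
            assert len(set(edges)) == 3
            g = nx.DiGraph(edges)
            assert nx.is_directed_acyclic_graph(g)

    def test_triangle_is_forced_transitive(self, rng):
        edges = random_dag(3, 3, rng)
        assert len(edges) == 3  # the unique DAG on 3 nodes with 3 edges


class TestGCP:
    def _planted(self, rng, n=50, b=0.8, n_nodes=6):
        genes = [f"g{i}" for i in range(n_nodes)]
        edges = [(genes[i], genes[i + 1]) for i in range(n_nodes - 1)]
        data = np.empty((n_nodes, n))
        data[0] = rng.normal(size=n)
        for i in range(1, n_nodes):
            data[i] = b * data[i - 1] + rng.normal(size=n)
        return (
            RegulatoryNetwork("chain", "chain", frozenset(edges)),
            make_dataset(data, genes=genes),
        )

    def test_planted_network_significant(self, rng):
        net, ds = self._planted(rng)
        res = gcp(net, ds, n_random=200, alpha=0.05, rng=rng)
        assert res.gcp < 0.05 and res.significant

    def test_seed_determinism(self, rng):
        net, ds = self._planted(rng)
        a = gcp(net, ds, n_random=50, rng=np.random.default_rng(42))
        b = gcp(net, ds, n_random=50, rng=np.random.default_rng(42))
        assert (a.n_better, a.gcp, a.observed_loglik) == (
            b.n_better, b.gcp, b.observed_loglik
        )

    def test_gcp_bounds_and_consistency(self, rng):
        net, ds = self._planted(rng, n=12, b=0.3)
        res = gcp(net, ds, n_random=100, rng=rng)
        assert 0.0 <= res.gcp <= 1.0
        assert res.gcp == res.n_better / res.n_random

    def test_null_gcp_roughly_uniform(self, rng):
        """Random structure scored on i.i.d. noise: GCP ~ Uniform[0,1]."""
        gcps = []
        genes = [f"g{i}" for i in range(6)]
        for _ in range(60):
            data = rng.normal(size=(6, 15))
            ds = make_dataset(data, genes=genes)
            edges = random_dag(6, 6, rng)
            net = RegulatoryNetwork(
                "r", "r", frozenset({(genes[a], genes[b]) for a, b in edges})
            )
            gcps.append(gcp(net, ds, n_random=60, rng=rng).gcp)
        p = stats.kstest(gcps, "uniform").pvalue
        assert p > 0.01

    def test_screen_collection_planted_cell_only(self, rng):
        """A network planted in case-P2 is flagged there and not elsewhere."""
        genes = ["t1", "x1", "x2", "x3"]
        net = RegulatoryNetwork(
            "planted", "planted",
            frozenset({("t1", "x1"), ("t1", "x2"), ("t1", "x3")}),
        )

        def tweak(strain, period, block):
            if (strain, period) == ("case", "P2"):
                for i in range(1, 4):
                    block[i] = 1.2 * block[0] + 0.4 * block[i]

        ds = make_six_cell_dataset(rng, genes, n_per_cell=40, tweak=tweak)
        results = screen_collection([net], ds, n_random=100, seed=3)
        assert results[("case", "P2")][0].significant
        insignificant = [
            results[cell][0].significant
            for cell in results
            if cell != ("case", "P2")
        ]
        assert sum(insignificant) <= 1  # at most one chance hit elsewhere

    def test_screen_collection_deterministic(self, rng):
        genes = ["t1", "x1", "x2"]
        net = RegulatoryNetwork(
            "n", "n", frozenset({("t1", "x1"), ("t1", "x2")})
        )
        ds = make_six_cell_dataset(rng, genes, n_per_cell=10)
        r1 = screen_collection([net], ds, n_random=50, seed=11)
        r2 = screen_collection([net], ds, n_random=50, seed=11)
        for cell in r1:
            assert [x.n_better for x in r1[cell]] == [
                x.n_better for x in r2[cell]
            ]

    def test_empty_collection(self, rng):
        ds = make_six_cell_dataset(rng, ["a", "b"], n_per_cell=5)
        results = screen_collection([], ds, n_random=10, seed=0)
        assert all(v == [] for v in results.values())
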