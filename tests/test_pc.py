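"""Modified PC: partial correlations, scheduling, worked example, robustness."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from mrscreen.pc import (
    PCConfig,
    fisher_z_test,
    infer_cells,
    modified_pc,
    partial_corr,
)
from mrscreen.synthdata import (
    FIVE_NODE_EDGES,
    correlation_from_covariance,
    five_node_demo_correlation,
    sem_covariance,
)

from conftest import make_dataset, make_six_cell_dataset


# -- independent oracle: the first-order recursion formula, applied recursively


def recursion_partial_corr(corr, i, j, S):
    if not S:
        return corr[i, j]
    k, rest = S[0], S[1:]
    rij = recursion_partial_corr(corr, i, j, rest)
    rik = recursion_partial_corr(corr, i, k, rest)
    rjk = recursion_partial_corr(corr, j, k, rest)
    return (rij - rik * rjk) / np.sqrt((1 - rik**2) * (1 - rjk**2))


def random_correlation(rng, p):
    A = rng.normal(size=(p, p + 3))
    S = A @ A.T / (p + 3)
    return correlation_from_covariance(S)


class TestPartialCorr:
    def test_identity_matrix_gives_zero(self):
        r, ok = partial_corr(np.eye(4), 0, 1, [2, 3])
        assert ok and r == pytest.approx(0.0)

    def test_first_order_textbook_value(self):
        corr = np.array(
            [[1.0, 0.6, 0.5], [0.6, 1.0, 0.5], [0.5, 0.5, 1.0]]
        )
        r, ok = partial_corr(corr, 0, 1, [2])
        assert ok
        assert r == pytest.approx((0.6 - 0.25) / (1 - 0.25), abs=1e-12)

    def test_duplicated_variable_fails_cleanly(self):
        base = np.array([[1.0, 0.3], [0.3, 1.0]])
        corr = np.ones((3, 3))
        corr[:2, :2] = base
        corr[2, :2] = base[0]
        corr[:2, 2] = base[0]
        corr[2, 2] = 1.0  # variable 2 duplicates variable 0
        _, ok = partial_corr(corr, 0, 2, [1])
        assert not ok

    def test_matches_recursion_oracle(self, rng):
        """Inversion route equals the recursion formula, orders <= 3."""
        for _ in range(100):
            corr = random_correlation(rng, 6)
            order = int(rng.integers(0, 4))
            idx = rng.permutation(6)[: order + 2]
            i, j, S = int(idx[0]), int(idx[1]), [int(x) for x in idx[2:]]
            r, ok = partial_corr(corr, i, j, S)
            if not ok:
                continue
            expected = recursion_partial_corr(corr, i, j, tuple(S))
            assert r == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestFisherZ:
    def test_zero_correlation(self):
        p, indep = fisher_z_test(0.0, 30, 0, 0.05)
        assert p == pytest.approx(1.0) and indep

    def test_closed_form_value(self):
        # 2 * Phi(-sqrt(27) * atanh(0.5)), computed independently
        p, indep = fisher_z_test(0.5, 30, 0, 0.05)
        expected = 2 * stats.norm.cdf(-np.sqrt(27) * np.arctanh(0.5))
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.004313, abs=2e-6)
        assert not indep

    def test_near_unit_correlation_dependent(self):
        p, indep = fisher_z_test(1 - 1e-9, 30, 0, 0.05)
        assert p < 1e-12 and not indep


class TestWorkedExample:
    """Five-variable collider/chain model with known independences."""

    def test_removal_schedule_and_final_skeleton(self):
        corr, names = five_node_demo_correlation()
        sk = modified_pc(
            corr=corr, var_names=names,
            config=PCConfig(mode="oracle-covariance"),
        )
        by_order = {}
        for rec in sk.removal_log:
            by_order.setdefault(rec.order, set()).add(rec.pair)
        assert by_order[0] == {("X1", "X2"), ("X2", "X4")}
        assert by_order[1] == {("X3", "X4")}
        assert by_order[2] == {("X1", "X5"), ("X2", "X5")}
        assert sk.edges == {tuple(sorted(e)) for e in FIVE_NODE_EDGES}
        assert not sk.retained_flags

    def test_sepsets_certify_the_independences(self):
        corr, names = five_node_demo_correlation()
        sk = modified_pc(
            corr=corr, var_names=names,
            config=PCConfig(mode="oracle-covariance"),
        )
        sepsets = {rec.pair: set(rec.sepset) for rec in sk.removal_log}
        assert sepsets[("X3", "X4")] <= {"X1", "X2"}
        assert sepsets[("X1", "X5")] == {"X3", "X4"}
        assert sepsets[("X2", "X5")] == {"X3", "X4"}

    def test_removal_sizes_match_order(self):
        corr, names = five_node_demo_correlation()
        sk = modified_pc(
            corr=corr, var_names=names,
            config=PCConfig(mode="oracle-covariance"),
        )
        assert all(len(r.sepset) == r.order for r in sk.removal_log)


def dsep_skeleton(edges, names):
    """Brute-force faithful skeleton: adjacency iff no subset d-separates."""
    g = nx.DiGraph()
    g.add_nodes_from(names)
    g.add_edges_from(edges)
    keep = set()
    for a, b in itertools.combinations(names, 2):
        rest = [x for x in names if x not in (a, b)]
        separable = any(
            nx.is_d_separator(g, {a}, {b}, set(S))
            for k in range(len(rest) + 1)
            for S in itertools.combinations(rest, k)
        )
        if not separable:
            keep.add(tuple(sorted((a, b))))
    return keep


class TestOracleModeConsistency:
    def test_random_linear_gaussian_dags(self, rng):
        """Oracle-mode PC recovers the d-separation skeleton exactly."""
        names = ("V1", "V2", "V3", "V4", "V5")
        for _ in range(20):
            order = rng.permutation(5)
            edges = []
            B = np.zeros((5, 5))
            for ai, bi in itertools.combinations(range(5), 2):
                if rng.random() < 0.4:
                    a, b = int(order[ai]), int(order[bi])
                    edges.append((names[a], names[b]))
                    B[a, b] = rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
            corr = correlation_from_covariance(sem_covariance(B, np.ones(5)))
            sk = modified_pc(
                corr=corr, var_names=names,
                config=PCConfig(mode="oracle-covariance", zero_tol=1e-7),
            )
            assert sk.edges == dsep_skeleton(edges, names)


class TestRobustness:
    def test_duplicated_gene_flagged_not_fatal(self, rng):
        """A gene present under two names terminates with a flagged edge."""
        base = rng.normal(size=(4, 25))
        data = np.vstack([base, base[0]])  # g5 duplicates g1
        ds = make_dataset(data, genes=["g1", "g2", "g3", "g4", "g5"])
        sk = modified_pc(ds, config=PCConfig())
        assert ("g1", "g5") in sk.edges
        assert ("g1", "g5") in sk.retained_flags

    def test_rank_deficient_never_aborts(self, rng):
        base = rng.normal(size=(3, 10))
        data = np.vstack([base, base[0] + base[1], np.full(10, 2.0)])
        ds = make_dataset(data, genes=["a", "b", "c", "d", "konst"])
        sk = modified_pc(ds, config=PCConfig())
        assert "konst" in sk.dropped_constant

    def test_single_sample_cell_returns_complete_graph(self):
        ds = make_dataset(np.array([[1.0], [2.0], [3.0]]))
        sk = modified_pc(ds, config=PCConfig())
        assert len(sk.edges) == 3 and sk.skipped_tests

    def test_audit_log_consistency(self, rng):
        data = rng.normal(size=(6, 20))
        ds = make_dataset(data)
        sk = modified_pc(ds, config=PCConfig())
        removed = {tuple(sorted(r.pair)) for r in sk.removal_log}
        assert removed.isdisjoint(sk.edges)
        complete = {
            tuple(sorted(p))
            for p in itertools.combinations(sk.nodes, 2)
        }
        assert sk.edges | removed == complete
        assert sk.retained_flags <= sk.edges


class TestInferCells:
    def test_identical_cells_identical_skeletons(self, rng):
        genes = ["a", "b", "c", "d"]
        block = rng.normal(size=(4, 8))

        ds = make_six_cell_dataset(
            rng, genes, n_per_cell=8,
            tweak=lambda s, p, blk: blk.__setitem__(slice(None), block),
        )
        sks = infer_cells(ds, PCConfig())
        first = sks[("case", "P1")]
        for sk in sks.values():
            assert sk.edges == first.edges

    def test_planted_edges_enriched_in_case(self, rng):
        """Case-only regulation yields more planted edges in case skeletons."""
        genes = ["tf", "x1", "x2", "x3", "x4"]

        def tweak(strain, period, block):
            if strain == "case":
                for i in range(1, 5):
                    block[i] = block[0] + 0.7 * block[i]

        ds = make_six_cell_dataset(rng, genes, n_per_cell=30, tweak=tweak)
        sks = infer_cells(ds, PCConfig())
        planted = {tuple(sorted(("tf", f"x{i}"))) for i in range(1, 5)}
        case_hits = sum(
            len(planted & sks[("case", p)].edges) for p in ("P1", "P2", "P3")
        )
        control_hits = sum(
            len(planted & sks[("control", p)].edges)
            for p in ("P1", "P2", "P3")
        )
        assert case_hits > control_hits
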