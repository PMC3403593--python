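"""Synthetic inputs: reference networks, TF lists, and planted expression data.

The generator emulates the statistical structure the analysis assumes — a
linear Gaussian structural equation model (SEM) with case-specific active
edges and differentially expressed targets — so that every pipeline stage
is exercisable without any download, and recovery failures are
attributable to the pipeline rather than to model mismatch.

A :class:`Scenario` plants a handful of master regulators (MRs) among the
TFs.  Each planted MR owns a regulon gene set whose edges carry the
regulatory coefficient only in the *case* cells of the MR's assigned
period (assigned round-robin over P1..P3); its targets are additionally
mean-shifted there, so they enter that period's expression signature.
Background TFs regulate their targets in every cell with the same
coefficient, and a fixed fraction of background targets is mean-shifted in
the case cells of all periods — these genes populate the signatures and
coverage tables of both strains and so exercise the specificity and
coverage criteria without ever being master regulators.  The remaining
genes are unregulated noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .iodata import (
    CELLS,
    ExpressionDataset,
    RegulatoryNetwork,
    canon,
    write_edge_list,
    write_expression,
    write_gene_sets,
    write_tf_list,
)

log = logging.getLogger(__name__)

PERIOD_CYCLE = ("P1", "P2", "P3")


@dataclass(frozen=True)
class Scenario:
    """Parameters of a planted-MR study.

    Defaults describe the demo scenario: 25 TFs of which 5 are planted MRs
    (round-robin over periods), MR regulons of 10 genes, 20 background
    regulon sets of 4 genes (half of each set differentially expressed),
    10 leftover unregulated genes, 50 samples per strain-by-period cell,
    unit regulatory coefficients, a 2.5-SD case shift on differential
    targets, and unit observation noise.
    """

    n_tfs: int = 25
    n_genes: int = 140
    n_networks: int = 25
    genes_per_set: int = 4
    mr_targets: int = 10
    n_samples: int = 50
    planted_mrs: tuple[str, ...] = ("TF01", "TF02", "TF03", "TF04", "TF05")
    effect_size: float = 1.0
    de_shift: float = 2.5
    noise_sd: float = 1.0
    background_de_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for name in ("n_tfs", "n_genes", "n_networks", "genes_per_set",
                     "mr_targets", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not set(self.planted_mrs) <= set(self.tf_symbols):
            raise ValueError("planted_mrs must be drawn from the TF symbols")

    @property
    def tf_symbols(self) -> tuple[str, ...]:
        return tuple(f"TF{i + 1:02d}" for i in range(self.n_tfs))

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1:03d}" for i in range(self.n_genes))

    def mr_period(self, mr: str) -> str:
        """Period (round-robin) in which a planted MR's edges are active."""
        return PERIOD_CYCLE[self.planted_mrs.index(mr) % len(PERIOD_CYCLE)]


@dataclass(frozen=True)
class ReferenceCollection:
    networks: tuple[RegulatoryNetwork, ...]
    gene_sets: tuple[tuple[str, str, tuple[str, ...]], ...]
    relations: tuple[tuple[str, str], ...]
    tf_list: tuple[str, ...]
    #: gene -> (regulator TF, active_period or None for always-active)
    regulation: Mapping[str, tuple[str, str | None]]
    #: genes mean-shifted in case cells; value = period or None (all periods)
    shifted: Mapping[str, str | None]


def make_reference_collection(
    scenario: Scenario, rng: np.random.Generator | None = None
) -> ReferenceCollection:
    """Build the gene sets, global relations, TF list and derived networks.

    The first ``len(planted_mrs)`` gene sets are MR regulons of
    ``mr_targets`` genes; the remaining sets hold ``genes_per_set`` genes
    each, regulated by the background TFs round-robin.  Gene sets are
    disjoint, so each set's network is exactly the relations targeting its
    members and every network passes collection validation by
    construction.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    mrs = scenario.planted_mrs
    background_tfs = [t for t in scenario.tf_symbols if t not in mrs]
    n_background_sets = scenario.n_networks - len(mrs)
    if n_background_sets < 0:
        raise ValueError("n_networks smaller than the number of planted MRs")
    if n_background_sets and not background_tfs:
        raise ValueError("background sets requested but every TF is a planted MR")
    needed = len(mrs) * scenario.mr_targets + n_background_sets * scenario.genes_per_set
    if needed > scenario.n_genes:
        raise ValueError(
            f"gene pool too small: need {needed}, have {scenario.n_genes}"
        )

    genes = list(scenario.gene_symbols)
    cursor = 0
    gene_sets: list[tuple[str, str, tuple[str, ...]]] = []
    relations: list[tuple[str, str]] = []
    regulation: dict[str, tuple[str, str | None]] = {}
    shifted: dict[str, str | None] = {}

    for mr in mrs:
        members = tuple(genes[cursor:cursor + scenario.mr_targets])
        cursor += scenario.mr_targets
        period = scenario.mr_period(mr)
        gene_sets.append((f"regulon_{mr}", f"planted regulon of {mr}", members))
        for g in members:
            relations.append((mr, g))
            regulation[g] = (mr, period)
            shifted[g] = period

    for k in range(n_background_sets):
        members = tuple(genes[cursor:cursor + scenario.genes_per_set])
        cursor += scenario.genes_per_set
        gene_sets.append(
            (f"background_set_{k + 1:03d}", "background gene set", members)
        )
        for gi, g in enumerate(members):
            tf = background_tfs[(k * scenario.genes_per_set + gi) % len(background_tfs)]
            relations.append((tf, g))
            regulation[g] = (tf, None)
            # stagger the differential positions across sets so that every
            # background TF ends up with ~the same fraction of shifted targets
            if (k + gi) % len(members) < scenario.background_de_fraction * len(members):
                shifted[g] = None  # differential in every period

    networks = tuple(
        RegulatoryNetwork(
            network_id=name,
            name=name,
            edges=frozenset(
                (tf, tg) for tf, tg in relations
                if canon(tg) in {canon(m) for m in members}
            ),
        )
        for name, _desc, members in gene_sets
    )
    return ReferenceCollection(
        networks=networks,
        gene_sets=tuple(gene_sets),
        relations=tuple(relations),
        tf_list=scenario.tf_symbols,
        regulation=regulation,
        shifted=shifted,
    )


def simulate_expression(
    scenario: Scenario,
    collection: ReferenceCollection,
    rng: np.random.Generator | None = None,
) -> ExpressionDataset:
    """Simulate all six strain-by-period cells from the linear Gaussian SEM.

    Per cell and per sample: root TFs are standard normal; each regulated
    gene is ``effect_size * parent + N(0, noise_sd)`` when its edge is
    active in the cell, pure noise otherwise; differential genes get the
    ``de_shift`` mean offset in the matching case cells.  Samples are
    independent; a fixed scenario seed reproduces the dataset bit-exactly.
    """
    rng = rng or np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(1,))
    )
    tf_syms = scenario.tf_symbols
    gene_syms = scenario.gene_symbols
    all_syms = tf_syms + gene_syms
    n = scenario.n_samples

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    meta: dict[str, tuple[str, str]] = {}
    for strain, period in CELLS:
        tf_vals = rng.normal(size=(len(tf_syms), n))
        tf_row = {t: tf_vals[i] for i, t in enumerate(tf_syms)}
        block = np.empty((len(all_syms), n))
        block[: len(tf_syms)] = tf_vals
        for gi, g in enumerate(gene_syms):
            noise = rng.normal(scale=scenario.noise_sd, size=n)
            reg = collection.regulation.get(g)
            active = (
                reg is not None
                and (
                    reg[1] is None
                    or (strain == "case" and period == reg[1])
                )
            )
            x = noise + (scenario.effect_size * tf_row[reg[0]] if active else 0.0)
            shift_period = collection.shifted.get(g, "missing")
            if shift_period != "missing" and strain == "case" and (
                shift_period is None or shift_period == period
            ):
                x = x + scenario.de_shift * scenario.noise_sd
            block[len(tf_syms) + gi] = x
        for k in range(n):
            sid = f"{strain}_{period}_{k + 1:02d}"
            sample_ids.append(sid)
            meta[sid] = (strain, period)
        columns.append(block)

    values = np.concatenate(columns, axis=1)
    return ExpressionDataset(
        gene_ids=all_syms,
        sample_ids=tuple(sample_ids),
        values=values,
        sample_meta=meta,
    )


def end_to_end_truth(scenario: Scenario) -> frozenset[str]:
    """Expected final candidate set for the recovery harness."""
    return frozenset(scenario.planted_mrs)


def write_scenario_artifacts(
    scenario: Scenario, out_dir: str | Path
) -> ReferenceCollection:
    """Generate and persist every iodata artifact for a scenario."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collection = make_reference_collection(scenario)
    dataset = simulate_expression(scenario, collection)
    write_gene_sets(collection.gene_sets, out / "gene_sets.gmt")
    write_edge_list(collection.relations, out / "relations.tsv")
    write_tf_list(collection.tf_list, out / "tfs.txt")
    write_expression(dataset, out / "expression.tsv", out / "samples.tsv")
    return collection


# ---------------------------------------------------------------------------
# closed-form SEM machinery and the five-variable demonstration model
# ---------------------------------------------------------------------------


def sem_covariance(B: np.ndarray, noise_var: np.ndarray) -> np.ndarray:
    """Population covariance of the linear SEM  x = B^T x + e.

    ``B[i, j]`` is the coefficient on parent i in child j's equation;
    ``noise_var`` holds the noise variances.  The covariance is
    (I - B^T)^{-1} diag(noise_var) (I - B)^{-1}.
    """
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    A = np.linalg.inv(np.eye(p) - B.T)
    return A @ np.diag(np.asarray(noise_var, dtype=float)) @ A.T


def correlation_from_covariance(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


#: edges of the five-variable collider demonstration DAG
FIVE_NODE_EDGES: tuple[tuple[str, str], ...] = (
    ("X1", "X3"),
    ("X2", "X3"),
    ("X1", "X4"),
    ("X3", "X5"),
    ("X4", "X5"),
)


def five_node_demo_correlation(
    coefficients: Mapping[tuple[str, str], float] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Population correlation of the five-variable demonstration SEM.

    The DAG X1 -> X3 <- X2, X1 -> X4, X3 -> X5 <- X4 encodes exactly the
    conditional independences a correctly working PC run must recover:
    X1 and X2 marginally independent; X2 independent of X4; X3 and X4
    independent given X1; X5 independent of X1 and of X2 given (X3, X4).
    Default coefficients are faithful (no accidental cancellations).
    """
    names = ("X1", "X2", "X3", "X4", "X5")
    coeff = {
        ("X1", "X3"): 0.8,
        ("X2", "X3"): 0.8,
        ("X1", "X4"): 0.7,
        ("X3", "X5"): 0.6,
        ("X4", "X5"): 0.7,
    }
    if coefficients:
        coeff.update(coefficients)
    idx = {n: i for i, n in enumerate(names)}
    B = np.zeros((5, 5))
    for (a, b), w in coeff.items():
        B[idx[a], idx[b]] = w
    S = sem_covariance(B, np.ones(5))
    return correlation_from_covariance(S), names
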