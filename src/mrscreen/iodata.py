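"""Readers and writers for every on-disk artifact of the pipeline.

Formats handled here are all plain text, UTF-8, tab-delimited:

* GMT gene-set files (name, description, member genes per line);
* TF->target edge lists (TSV, columns ``tf`` and ``target``);
* expression matrices (TSV, genes in rows, header row of sample ids);
* sample sheets (TSV, columns ``sample_id``, ``strain``, ``period``);
* plain-text TF lists (one symbol per line);
* result tables written by :func:`write_report` plus a JSON run summary.

Gene symbol matching is case-insensitive throughout: symbols are case-folded
at ingest and compared on the folded form, while the original casing is kept
for display.  Mixed-case duplicates (``Sp2`` vs ``SP2``) are therefore
treated as collisions in an expression matrix and as the same gene in
network construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STRAINS = ("case", "control")
PERIODS = ("P1", "P2", "P3")
#: the six strain-by-period analysis cells, in canonical order
CELLS = tuple((s, p) for s in STRAINS for p in PERIODS)

Cell = tuple[str, str]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


def canon(symbol: str) -> str:
    """Canonical (case-folded, stripped) form of a gene/TF symbol."""
    return symbol.strip().casefold()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulatoryNetwork:
    """A named directed TF->gene network from the reference collection.

    ``edges`` are ordered (tf_symbol, target_symbol) pairs.  Networks used
    for likelihood screening must be acyclic; this is validated at
    construction.  Self-loops are always rejected.
    """

    network_id: str
    name: str
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for tf, tg in self.edges:
            if canon(tf) == canon(tg):
                raise FormatError(
                    f"network {self.network_id!r}: self-loop on {tf!r}"
                )
        g = self.to_digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(
                f"network {self.network_id!r} is cyclic (e.g. {cycle})"
            )

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for tf, tg in self.edges:
            g.add_edge(canon(tf), canon(tg))
        return g

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.edges}

    @property
    def nodes(self) -> set[str]:
        """All distinct symbols (display casing) appearing in edges."""
        seen: dict[str, str] = {}
        for tf, tg in sorted(self.edges):
            seen.setdefault(canon(tf), tf)
            seen.setdefault(canon(tg), tg)
        return set(seen.values())

    @property
    def n_nodes(self) -> int:
        return len({canon(s) for e in self.edges for s in e})

    @property
    def n_edges(self) -> int:
        return len({(canon(a), canon(b)) for a, b in self.edges})


@dataclass(frozen=True)
class ExpressionDataset:
    """Genes x samples expression matrix with strain/period sample metadata.

    ``values[i, k]`` is the (log-scale) expression of gene ``gene_ids[i]``
    in sample ``sample_ids[k]``.  ``sample_meta`` maps each sample id to a
    ``(strain, period)`` pair with strain in {case, control} and period in
    {P1, P2, P3}.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    sample_meta: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(vals)):
            i, k = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[k]!r}"
            )
        folded: dict[str, str] = {}
        for g in self.gene_ids:
            c = canon(g)
            if c in folded:
                raise FormatError(
                    f"duplicate gene symbol after case-folding: "
                    f"{folded[c]!r} / {g!r}"
                )
            folded[c] = g
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        for s in self.sample_ids:
            if s not in self.sample_meta:
                raise FormatError(f"sample {s!r} missing from sample sheet")
            strain, period = self.sample_meta[s]
            if strain not in STRAINS:
                raise FormatError(f"sample {s!r}: unknown strain {strain!r}")
            if period not in PERIODS:
                raise FormatError(f"sample {s!r}: unknown period {period!r}")
        object.__setattr__(self, "_gene_index", {canon(g): i for i, g in enumerate(self.gene_ids)})

    # -- convenience views -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, symbol: str) -> int | None:
        """Row index of ``symbol`` (case-insensitive), or None if absent."""
        return self._gene_index.get(canon(symbol))

    def select_samples(self, keep: Sequence[str]) -> "ExpressionDataset":
        idx = [self.sample_ids.index(s) for s in keep]
        return ExpressionDataset(
            gene_ids=self.gene_ids,
            sample_ids=tuple(keep),
            values=self.values[:, idx],
            sample_meta={s: self.sample_meta[s] for s in keep},
        )

    def cell(self, strain: str, period: str) -> "ExpressionDataset":
        """Restrict to the samples of one strain x period cell."""
        keep = [
            s
            for s in self.sample_ids
            if self.sample_meta[s] == (strain, period)
        ]
        return self.select_samples(keep)

    def period_view(self, period: str) -> "ExpressionDataset":
        """Restrict to all samples (both strains) of one period."""
        keep = [
            s for s in self.sample_ids if self.sample_meta[s][1] == period
        ]
        return self.select_samples(keep)

    def strain_of(self, sample_id: str) -> str:
        return self.sample_meta[sample_id][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


# ---------------------------------------------------------------------------
# expression matrix + sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(sheet_path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    required = {"sample_id", "strain", "period"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(required)}, "
            f"got {list(sheet.columns)}"
        )
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample id in sheet: {dup!r}")
    if sheet[["strain", "period"]].isna().any().any():
        raise FormatError("sample sheet has missing strain/period entries")
    return sheet


def read_expression(
    matrix_path: str | Path, sheet_path: str | Path
) -> ExpressionDataset:
    """Read an expression matrix and its sample sheet into a validated dataset.

    The matrix is TSV with a header row of sample ids and gene symbols in
    the first column.  The sample-id sets of matrix and sheet must match
    exactly; any discrepancy is reported by name.  Non-numeric cells are
    reported with their (gene, sample) coordinates.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    sheet = read_sample_sheet(sheet_path)

    matrix_samples = set(raw.columns)
    sheet_samples = set(sheet["sample_id"])
    missing_in_matrix = sorted(sheet_samples - matrix_samples)
    missing_in_sheet = sorted(matrix_samples - sheet_samples)
    if missing_in_matrix:
        raise FormatError(
            f"sample {missing_in_matrix[0]!r} listed in sheet but absent "
            f"from matrix"
        )
    if missing_in_sheet:
        raise FormatError(
            f"sample {missing_in_sheet[0]!r} present in matrix but absent "
            f"from sheet"
        )

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[np.flatnonzero(bad.to_numpy())[0]]
            raise FormatError(
                f"non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        values[:, j] = converted.to_numpy()

    meta = {
        row.sample_id: (row.strain, row.period)
        for row in sheet.itertuples()
    }
    return ExpressionDataset(
        gene_ids=tuple(str(g) for g in raw.index),
        sample_ids=tuple(raw.columns),
        values=values,
        sample_meta=meta,
    )


def write_expression(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    sheet_path: str | Path,
) -> None:
    dataset.to_frame().to_csv(matrix_path, sep="\t", index_label="gene")
    rows = [
        {"sample_id": s, "strain": dataset.sample_meta[s][0],
         "period": dataset.sample_meta[s][1]}
        for s in dataset.sample_ids
    ]
    pd.DataFrame(rows).to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets, edge lists, TF lists, network construction
# ---------------------------------------------------------------------------


def read_gene_sets(gmt_path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Parse a GMT file into (name, description, members) triples.

    Standard dialect: two leading columns (set name, free-text description,
    possibly empty) followed by member gene symbols, all tab-separated.
    """
    sets: list[tuple[str, str, list[str]]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(
        Path(gmt_path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(
                f"{gmt_path}:{lineno}: GMT line needs name, description and "
                f"at least one member gene"
            )
        name, description, *genes = parts
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise FormatError(f"{gmt_path}:{lineno}: gene set {name!r} empty")
        if name in seen:
            raise FormatError(f"duplicate gene-set name {name!r}")
        seen.add(name)
        sets.append((name, description, genes))
    return sets


def write_gene_sets(
    sets: Iterable[tuple[str, str, Sequence[str]]], gmt_path: str | Path
) -> None:
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for name, description, genes in sets:
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_edge_list(edges_path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(edges_path, sep="\t", dtype=str)
    if not {"tf", "target"}.issubset(df.columns):
        raise FormatError("edge list must have columns 'tf' and 'target'")
    if df.empty:
        raise FormatError(f"edge list {edges_path} is empty")
    return [(row.tf, row.target) for row in df.itertuples()]


def write_edge_list(
    edges: Iterable[tuple[str, str]], edges_path: str | Path
) -> None:
    pd.DataFrame(sorted(edges), columns=["tf", "target"]).to_csv(
        edges_path, sep="\t", index=False
    )


def read_tf_list(tf_list_path: str | Path) -> list[str]:
    tfs = [
        line.strip()
        for line in Path(tf_list_path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    if not tfs:
        raise FormatError(f"TF list {tf_list_path} is empty")
    return tfs


def write_tf_list(tfs: Iterable[str], tf_list_path: str | Path) -> None:
    Path(tf_list_path).write_text(
        "".join(f"{t}\n" for t in sorted(set(tfs))), encoding="utf-8"
    )


def _break_cycles(
    edges: set[tuple[str, str]], read_order: Mapping[tuple[str, str], int],
    network_id: str,
) -> set[tuple[str, str]]:
    """Delete, per cycle, the last-read edge closing it.  Logged."""
    edges = set(edges)
    while True:
        g = nx.DiGraph()
        for tf, tg in edges:
            g.add_edge(canon(tf), canon(tg))
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return edges
        cycle_edges = {(a, b) for a, b in cycle}
        candidates = [
            e for e in edges if (canon(e[0]), canon(e[1])) in cycle_edges
        ]
        victim = max(candidates, key=lambda e: read_order[e])
        edges.discard(victim)
        log.warning(
            "network %s: removed cycle-closing edge %s -> %s",
            network_id, victim[0], victim[1],
        )


def read_network_collection(
    gmt_path: str | Path,
    edges_path: str | Path,
    tf_list_path: str | Path,
    *,
    repair_cycles: bool = False,
) -> list[RegulatoryNetwork]:
    """Build one regulatory network per gene set from global binary relations.

    For each gene set the global TF->target relations are searched; every
    relation whose *target* lies in the set becomes an edge of that set's
    network.  Gene sets matching no relation are dropped (count logged).
    Every relation's TF must appear in the supplied TF list — TF identity is
    never inferred from topology.  Cyclic networks are rejected unless
    ``repair_cycles`` is set, in which case the last-read edge closing each
    cycle is deleted and logged.
    """
    gene_sets = read_gene_sets(gmt_path)
    relations = read_edge_list(edges_path)
    tf_canon = {canon(t) for t in read_tf_list(tf_list_path)}

    unknown = sorted({tf for tf, _ in relations if canon(tf) not in tf_canon})
    if unknown:
        raise FormatError(
            f"edge-list TFs absent from TF list: {unknown[:5]}"
        )
    read_order = {e: i for i, e in enumerate(relations)}

    networks: list[RegulatoryNetwork] = []
    dropped = 0
    for name, _description, genes in gene_sets:
        members = {canon(g) for g in genes}
        edges = {(tf, tg) for tf, tg in relations if canon(tg) in members}
        if not edges:
            dropped += 1
            continue
        if repair_cycles:
            edges = _break_cycles(edges, read_order, name)
        networks.append(
            RegulatoryNetwork(network_id=name, name=name, edges=frozenset(edges))
        )
    if dropped:
        log.info("dropped %d gene sets matching no relation", dropped)
    return sorted(networks, key=lambda n: n.network_id)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def write_skeletons(skeletons: Mapping[Cell, object], out_dir: str | Path) -> None:
    """Write per-cell skeleton edge lists and removal logs (TSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (strain, period), sk in skeletons.items():
        tag = f"{strain}_{period}"
        pd.DataFrame(
            [
                {
                    "gene_a": a,
                    "gene_b": b,
                    "flag": "kept-multicollinear"
                    if (a, b) in sk.retained_flags
                    else "",
                }
                for a, b in sorted(sk.edges)
            ],
            columns=["gene_a", "gene_b", "flag"],
        ).to_csv(out / f"skeleton_{tag}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "gene_a": rec.pair[0],
                    "gene_b": rec.pair[1],
                    "order": rec.order,
                    "sepset": ",".join(rec.sepset),
                    "statistic": rec.statistic,
                    "p": rec.p,
                }
                for rec in sk.removal_log
            ],
            columns=["gene_a", "gene_b", "order", "sepset", "statistic", "p"],
        ).to_csv(out / f"removals_{tag}.tsv", sep="\t", index=False)


def write_gcp_table(results: Sequence[object], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "network_id": r.network_id,
                "loglik": r.observed_loglik,
                "Ns": r.n_better,
                "Nr": r.n_random,
                "gcp": r.gcp,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["network_id", "loglik", "Ns", "Nr", "gcp", "significant"],
    ).to_csv(path, sep="\t", index=False)


_OVERLAP_ROWS = ("screening_specificity", "screening_coverage")
_OVERLAP_COLS = ("inference_specificity", "inference_coverage")


def write_overlap_matrix(matrix: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        np.asarray(matrix, dtype=int),
        index=list(_OVERLAP_ROWS),
        columns=list(_OVERLAP_COLS),
    ).to_csv(path, sep="\t", index_label="criterion")


def read_overlap_matrix(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.loc[list(_OVERLAP_ROWS), list(_OVERLAP_COLS)].to_numpy(dtype=int)


def write_report(report, out_dir: str | Path, summary: dict | None = None) -> None:
    """Persist a CandidateReport as TSV tables plus a JSON run summary.

    Emits the specificity TF lists for both methods, the per-cell coverage
    tables, the 2x2 criterion-overlap matrix, and the final TF ->
    regulated-gene table (one row per pair).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for fname, tfs in [
        ("specificity_screening.tsv", report.specificity_screening),
        ("specificity_inference.tsv", report.specificity_inference),
    ]:
        pd.DataFrame({"tf": sorted(tfs)}).to_csv(
            out / fname, sep="\t", index=False
        )

    for fname, tables in [
        ("coverage_screening.tsv", report.coverage_tables_screening),
        ("coverage_inference.tsv", report.coverage_tables_inference),
    ]:
        rows = []
        for (strain, period), table in sorted((tables or {}).items()):
            for r in table.rows:
                rows.append(
                    {
                        "strain": strain,
                        "period": period,
                        "tf": r.tf,
                        "n_regulated": r.n_regulated,
                        "grubbs_G": r.grubbs_G,
                        "selected": r.selected,
                    }
                )
        pd.DataFrame(
            rows,
            columns=["strain", "period", "tf", "n_regulated", "grubbs_G",
                     "selected"],
        ).to_csv(out / fname, sep="\t", index=False)

    write_overlap_matrix(report.overlap_matrix, out / "overlap_matrix.tsv")

    pd.DataFrame(
        sorted(report.final_pairs), columns=["tf", "gene"]
    ).to_csv(out / "final_candidates.tsv", sep="\t", index=False)

    payload = dict(summary or {})
    payload.setdefault("n_final_tfs", len(report.final_tfs))
    payload.setdefault("n_final_pairs", len(report.final_pairs))
    payload.setdefault(
        "n_final_unique_genes", len({canon(g) for _, g in report.final_pairs})
    )
    (out / "summary.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
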