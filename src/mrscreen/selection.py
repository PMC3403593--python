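"""TF-candidate selection: specificity, coverage, and the final merge.

From the screening side, TF->gene pairs are extracted from each cell's
active (GCP-significant) networks; from the inference side, from each
cell's skeleton edges having exactly one endpoint in the TF list (an edge
between two TFs yields both orientations).  In both cases only pairs whose
regulated gene belongs to the period's expression signature are kept —
only directly bound targets, since both sources carry direct relations.

Two criteria then narrow the TFs per source:

specificity   the TF emerged (with >= 1 extracted pair) in at least one
              case cell and in no control cell;
coverage      per cell, the number of signature genes each TF regulates is
              tabulated and the TFs with outlyingly large counts are
              selected by an iterated one-sided Smirnov-Grubbs test
              (p < 0.05); the candidate set is the union of case-cell
              selections minus the union of control-cell selections.

The final master-regulator candidates are the TFs lying in the pairwise
intersections of the two methods' two criterion sets (equivalently, TFs
passing at least one criterion under *both* methods), with their regulated
genes collected from the case-cell pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .iodata import CELLS, Cell, RegulatoryNetwork, canon
from .pc import Skeleton
from .signature import SignatureResult

log = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class TFGenePairSet:
    """Signature-filtered TF->gene pairs of one cell from one source."""

    source: str  # "screening" | "inference"
    cell: Cell
    pairs: frozenset[Pair]

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.pairs}

    @property
    def tf_canon(self) -> set[str]:
        return {canon(tf) for tf, _ in self.pairs}


@dataclass(frozen=True)
class CoverageRow:
    tf: str
    n_regulated: int
    grubbs_G: float
    selected: bool


@dataclass(frozen=True)
class CoverageTable:
    """Per-cell regulated-gene counts, sorted descending, Grubbs-annotated.

    Selected rows always form a prefix of the sorted order: the iterated
    maximum test can only ever accept values from the top down.
    """

    cell: Cell
    rows: tuple[CoverageRow, ...]

    @property
    def selected_tfs(self) -> set[str]:
        return {r.tf for r in self.rows if r.selected}


@dataclass(frozen=True)
class CandidateReport:
    specificity_screening: frozenset[str]
    coverage_screening: frozenset[str]
    specificity_inference: frozenset[str]
    coverage_inference: frozenset[str]
    overlap_matrix: np.ndarray  # 2x2: rows screening (spec, cov), cols inference
    final_tfs: frozenset[str]
    final_pairs: frozenset[Pair]
    coverage_tables_screening: Mapping[Cell, CoverageTable] | None = None
    coverage_tables_inference: Mapping[Cell, CoverageTable] | None = None

    @property
    def final_unique_genes(self) -> set[str]:
        return {canon(g) for _, g in self.final_pairs}


# ---------------------------------------------------------------------------
# pair extraction
# ---------------------------------------------------------------------------


def extract_pairs_screening(
    active: Mapping[Cell, Sequence[RegulatoryNetwork]],
    signatures: Mapping[str, SignatureResult],
    tf_list: Iterable[str],
) -> dict[Cell, TFGenePairSet]:
    """Signature-filtered TF->gene pairs from each cell's active networks."""
    tf_canon = {canon(t) for t in tf_list}
    out: dict[Cell, TFGenePairSet] = {}
    for cell in CELLS:
        strain, period = cell
        sig = signatures[period].signature_genes
        pairs = {
            (tf, gene)
            for network in active.get(cell, ())
            for tf, gene in network.edges
            if canon(tf) in tf_canon and canon(gene) in sig
        }
        out[cell] = TFGenePairSet(
            source="screening", cell=cell, pairs=frozenset(pairs)
        )
    return out


def extract_pairs_inference(
    skeletons: Mapping[Cell, Skeleton],
    signatures: Mapping[str, SignatureResult],
    tf_list: Iterable[str],
    *,
    tf_tf_both_directions: bool = True,
) -> dict[Cell, TFGenePairSet]:
    """Signature-filtered TF->gene pairs from each cell's skeleton.

    An undirected edge with exactly one TF endpoint is read as TF ->
    other-gene; an edge between two TFs yields both orientations (each kept
    only if its target is in the signature) unless disabled.
    """
    tf_canon = {canon(t) for t in tf_list}
    out: dict[Cell, TFGenePairSet] = {}
    for cell in CELLS:
        strain, period = cell
        sig = signatures[period].signature_genes
        pairs: set[Pair] = set()
        sk = skeletons[cell]
        for a, b in sk.edges:
            a_tf, b_tf = canon(a) in tf_canon, canon(b) in tf_canon
            oriented: list[Pair] = []
            if a_tf and b_tf:
                if tf_tf_both_directions:
                    oriented = [(a, b), (b, a)]
            elif a_tf:
                oriented = [(a, b)]
            elif b_tf:
                oriented = [(b, a)]
            for tf, gene in oriented:
                if canon(gene) in sig:
                    pairs.add((tf, gene))
        out[cell] = TFGenePairSet(
            source="inference", cell=cell, pairs=frozenset(pairs)
        )
    return out


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------


def specificity_select(
    pair_sets: Mapping[Cell, TFGenePairSet]
) -> frozenset[str]:
    """TFs emerging in >= 1 case cell and in no control cell.

    Membership is case-insensitive; the returned symbols use the display
    casing of their first (sorted) case-cell occurrence.
    """
    case_display: dict[str, str] = {}
    control: set[str] = set()
    for cell in CELLS:
        strain, _ = cell
        ps = pair_sets[cell]
        for tf in sorted(ps.tfs):
            if strain == "case":
                case_display.setdefault(canon(tf), tf)
            else:
                control.add(canon(tf))
    return frozenset(
        disp for c, disp in case_display.items() if c not in control
    )


# ---------------------------------------------------------------------------
# coverage (Smirnov-Grubbs)
# ---------------------------------------------------------------------------


def grubbs_max_test(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """One-sided Smirnov-Grubbs test of the sample maximum.

    G = (max - mean) / sd with the N-1 sample standard deviation; the
    critical value is  ((N-1)/sqrt(N)) * sqrt(t^2 / (N-2+t^2))  with t the
    upper alpha/N one-sided Student quantile at N-2 degrees of freedom.
    Returns (G, critical, is_outlier).  Zero spread means no outlier.
    """
    x = np.asarray(values, dtype=float)
    N = x.size
    if N < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    sd = x.std(ddof=1)
    t = stats.t.isf(alpha / N, N - 2)
    critical = (N - 1) / math.sqrt(N) * math.sqrt(t * t / (N - 2 + t * t))
    if sd == 0.0:
        log.info("Grubbs: zero spread; no outlier")
        return 0.0, critical, False
    G = float((x.max() - x.mean()) / sd)
    return G, critical, G > critical


def _iterated_grubbs(
    counts: Mapping[str, int], alpha: float
) -> tuple[set[str], dict[str, float]]:
    """Iterated one-sided max test: select, remove, repeat.

    The test statistic depends only on the values, so when several TFs tie
    at the outlying maximum they are all selected and removed together —
    this keeps the selection invariant to TF input ordering.
    Stops when the maximum is not an outlier or fewer than 3 values remain.
    """
    remaining = dict(counts)
    selected: set[str] = set()
    g_at_selection: dict[str, float] = {}
    while len(remaining) >= 3:
        values = np.array(sorted(remaining.values(), reverse=True), dtype=float)
        G, _crit, is_out = grubbs_max_test(values, alpha=alpha)
        if not is_out:
            break
        top = max(remaining.values())
        for tf in [t for t, c in remaining.items() if c == top]:
            selected.add(tf)
            g_at_selection[tf] = G
            del remaining[tf]
    return selected, g_at_selection


def coverage_select(
    pair_sets: Mapping[Cell, TFGenePairSet], alpha: float = 0.05
) -> tuple[dict[Cell, CoverageTable], frozenset[str]]:
    """Coverage tables per cell and the coverage-criterion TF candidates.

    Per cell, the regulated (signature) genes of each TF are counted and
    the outlyingly well-covered TFs are selected by the iterated one-sided
    Grubbs test; cells with fewer than 3 covered TFs select nothing
    (warning logged).  The candidate set is the union of case-cell
    selections minus the union of control-cell selections.
    """
    tables: dict[Cell, CoverageTable] = {}
    case_display: dict[str, str] = {}
    control: set[str] = set()
    for cell in CELLS:
        strain, _ = cell
        ps = pair_sets[cell]
        counts: dict[str, int] = {}
        for tf, _gene in ps.pairs:
            counts[tf] = counts.get(tf, 0) + 1
        if len(counts) >= 3:
            selected, gvals = _iterated_grubbs(counts, alpha)
        else:
            selected, gvals = set(), {}
            if counts:
                log.warning(
                    "cell %s: only %d TFs with coverage; no selection",
                    cell, len(counts),
                )
        rows = tuple(
            CoverageRow(
                tf=tf,
                n_regulated=c,
                grubbs_G=gvals.get(tf, float("nan")),
                selected=tf in selected,
            )
            for tf, c in sorted(
                counts.items(), key=lambda kv: (-kv[1], canon(kv[0]))
            )
        )
        tables[cell] = CoverageTable(cell=cell, rows=rows)
        for tf in sorted(selected):
            if strain == "case":
                case_display.setdefault(canon(tf), tf)
            else:
                control.add(canon(tf))
    candidates = frozenset(
        disp for c, disp in case_display.items() if c not in control
    )
    return tables, candidates


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------


def _intersect(a: Iterable[str], b: Iterable[str]) -> set[str]:
    """Case-insensitive intersection, keeping display casing from ``a``."""
    bc = {canon(x) for x in b}
    return {x for x in a if canon(x) in bc}


def merge_candidates(
    spec_screen: Iterable[str],
    cov_screen: Iterable[str],
    spec_infer: Iterable[str],
    cov_infer: Iterable[str],
    pair_sets: Mapping[Cell, TFGenePairSet] | Sequence[Mapping[Cell, TFGenePairSet]] = (),
    coverage_tables_screening: Mapping[Cell, CoverageTable] | None = None,
    coverage_tables_inference: Mapping[Cell, CoverageTable] | None = None,
) -> CandidateReport:
    """Merge the four criterion TF sets into the final candidate report.

    ``overlap_matrix[i][j]`` counts the intersection of screening criterion
    i (specificity, coverage) with inference criterion j.  The final TFs
    are the union of the four intersections, and the final pairs are all
    case-cell pairs (from any supplied pair-set mapping) whose TF is final.
    """
    spec_screen = frozenset(spec_screen)
    cov_screen = frozenset(cov_screen)
    spec_infer = frozenset(spec_infer)
    cov_infer = frozenset(cov_infer)

    cells_ss_si = _intersect(spec_screen, spec_infer)
    cells_ss_ci = _intersect(spec_screen, cov_infer)
    cells_cs_si = _intersect(cov_screen, spec_infer)
    cells_cs_ci = _intersect(cov_screen, cov_infer)
    overlap = np.array(
        [
            [len(cells_ss_si), len(cells_ss_ci)],
            [len(cells_cs_si), len(cells_cs_ci)],
        ],
        dtype=int,
    )
    final_display: dict[str, str] = {}
    for group in (cells_ss_si, cells_ss_ci, cells_cs_si, cells_cs_ci):
        for tf in sorted(group):
            final_display.setdefault(canon(tf), tf)
    final_tfs = frozenset(final_display.values())
    final_canon = set(final_display)

    if isinstance(pair_sets, Mapping):
        pair_maps: Sequence[Mapping[Cell, TFGenePairSet]] = [pair_sets]
    else:
        pair_maps = list(pair_sets)
    final_pairs: set[Pair] = set()
    for pm in pair_maps:
        for (strain, _period), ps in pm.items():
            if strain != "case":
                continue
            for tf, gene in ps.pairs:
                if canon(tf) in final_canon:
                    final_pairs.add((final_display[canon(tf)], gene))

    return CandidateReport(
        specificity_screening=spec_screen,
        coverage_screening=cov_screen,
        specificity_inference=spec_infer,
        coverage_inference=cov_infer,
        overlap_matrix=overlap,
        final_tfs=final_tfs,
        final_pairs=frozenset(final_pairs),
        coverage_tables_screening=coverage_tables_screening,
        coverage_tables_inference=coverage_tables_inference,
    )
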