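"""Bundled selection tables from the GK/WKY diabetic-rat case study.

The package ships the published TF selection tables of the spontaneously
diabetic Goto-Kakizaki (GK) versus Wistar-Kyoto (WKY) rat analysis as
plain-text data: the specificity TF lists of both methods, the per-cell
coverage tables (regulated-gene counts of the Grubbs-selected TFs), and
the final candidate regulons.  They serve as a deterministic replay of the
criterion/merge logic — the upstream expression data and the licensed
reference-network collection are not redistributable, so the selection
stage is exercised on its printed inputs.

Cell labels are mapped to this package's vocabulary: GK -> ``case``,
WKY -> ``control``; the growth periods 4w, 8w-12w and 16w-20w -> ``P1``,
``P2``, ``P3``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .iodata import CELLS, Cell, canon
from .selection import CandidateReport, TFGenePairSet, merge_candidates

_DATA = resources.files("mrscreen") / "data" / "gk_case_study"


def _read_lines(name: str) -> list[str]:
    with resources.as_file(_DATA / name) as path:
        return [
            line.strip()
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA / name) as path:
        return pd.read_csv(path, sep="\t", dtype={"n_regulated": int})


def load_specific_tfs(source: str) -> frozenset[str]:
    """Published specificity-criterion TF set ('screening' or 'inference')."""
    return frozenset(_read_lines(f"{source}_specific_tfs.txt"))


def load_coverage_table(source: str) -> pd.DataFrame:
    """Published per-cell coverage counts of the Grubbs-selected TFs."""
    return _read_tsv(f"{source}_coverage.tsv")


def load_final_regulons() -> pd.DataFrame:
    """Published final candidate TF -> regulated-gene pairs."""
    return _read_tsv("final_regulons.tsv")


def coverage_candidates(table: pd.DataFrame) -> frozenset[str]:
    """Coverage-criterion candidates from a published coverage table.

    The published tables list the TFs already selected per cell, so the
    remaining rule is the strain difference: union of case-cell TFs minus
    union of control-cell TFs (case-insensitive).
    """
    case_display: dict[str, str] = {}
    control: set[str] = set()
    for row in table.itertuples():
        if row.strain == "case":
            case_display.setdefault(canon(row.tf), row.tf)
        else:
            control.add(canon(row.tf))
    return frozenset(
        disp for c, disp in case_display.items() if c not in control
    )


def replay_published_selection() -> CandidateReport:
    """Re-run the criterion overlap and merge on the published tables.

    The final pairs are taken from the published regulons restricted to the
    merged TFs; they are attached as a single case-cell pair set so that
    :func:`merge_candidates` applies its ordinary restriction rule.
    """
    spec_screen = load_specific_tfs("screening")
    spec_infer = load_specific_tfs("inference")
    cov_screen = coverage_candidates(load_coverage_table("screening"))
    cov_infer = coverage_candidates(load_coverage_table("inference"))

    regulons = load_final_regulons()
    pairs = frozenset(
        (row.tf, row.gene) for row in regulons.itertuples()
    )
    pair_sets: dict[Cell, TFGenePairSet] = {
        cell: TFGenePairSet(
            source="screening",
            cell=cell,
            pairs=pairs if cell == ("case", "P1") else frozenset(),
        )
        for cell in CELLS
    }
    return merge_candidates(
        spec_screen, cov_screen, spec_infer, cov_infer, pair_sets
    )
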