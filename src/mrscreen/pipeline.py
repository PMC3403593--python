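"""End-to-end orchestration: screen + infer -> signatures -> select -> merge.

The stages can be driven from on-disk artifacts (CLI) or in memory (the
recovery harness and tests).  One master seed governs every source of
randomness; per-network child seeds are derived inside
:func:`mrscreen.screening.screen_collection` by its documented counter
scheme, so repeated runs with the same configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import hierarchy as hierarchy_mod
from . import iodata, pc, screening, selection, signature, synthdata
from .iodata import CELLS, PERIODS, Cell, ExpressionDataset, RegulatoryNetwork

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Thresholds, sizes and toggles of a full pipeline run."""

    gcp_alpha: float = 0.05
    n_random: int = 2000
    pc_alpha: float = 0.05
    pc_max_order: int | None = None
    fdr: float = 0.05
    grubbs_alpha: float = 0.05
    seed: int = 0
    run_screening: bool = True
    run_inference: bool = True

    def __post_init__(self) -> None:
        for name in ("gcp_alpha", "pc_alpha", "grubbs_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1)")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must be in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    report: selection.CandidateReport
    signatures: Mapping[str, signature.SignatureResult]
    screen_results: Mapping[Cell, Sequence[screening.GCPResult]]
    skeletons: Mapping[Cell, pc.Skeleton]
    pairs_screening: Mapping[Cell, selection.TFGenePairSet]
    pairs_inference: Mapping[Cell, selection.TFGenePairSet]
    hierarchy_levels: hierarchy_mod.HierarchyLevels
    candidate_locations: object
    summary: dict


def run_pipeline(
    collection: Sequence[RegulatoryNetwork],
    dataset: ExpressionDataset,
    tf_list: Sequence[str],
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run every stage in memory and assemble the candidate report."""
    cfg = config or RunConfig()

    signatures = {
        p: signature.build_signature(dataset, p, cfg.fdr) for p in PERIODS
    }

    empty = {
        cell: selection.TFGenePairSet(
            source="screening", cell=cell, pairs=frozenset()
        )
        for cell in CELLS
    }
    if cfg.run_screening:
        screen_results = screening.screen_collection(
            collection, dataset, n_random=cfg.n_random,
            alpha=cfg.gcp_alpha, seed=cfg.seed,
        )
        active = screening.active_networks(collection, screen_results)
        pairs_screen = selection.extract_pairs_screening(
            active, signatures, tf_list
        )
    else:
        screen_results = {cell: [] for cell in CELLS}
        pairs_screen = empty

    if cfg.run_inference:
        skeletons = pc.infer_cells(
            dataset,
            pc.PCConfig(alpha=cfg.pc_alpha, max_order=cfg.pc_max_order),
        )
        pairs_infer = selection.extract_pairs_inference(
            skeletons, signatures, tf_list
        )
    else:
        skeletons = {}
        pairs_infer = {
            cell: selection.TFGenePairSet(
                source="inference", cell=cell, pairs=frozenset()
            )
            for cell in CELLS
        }

    spec_screen = selection.specificity_select(pairs_screen)
    cov_tables_screen, cov_screen = selection.coverage_select(
        pairs_screen, alpha=cfg.grubbs_alpha
    )
    spec_infer = selection.specificity_select(pairs_infer)
    cov_tables_infer, cov_infer = selection.coverage_select(
        pairs_infer, alpha=cfg.grubbs_alpha
    )

    report = selection.merge_candidates(
        spec_screen, cov_screen, spec_infer, cov_infer,
        [pairs_screen, pairs_infer],
        coverage_tables_screening=cov_tables_screen,
        coverage_tables_inference=cov_tables_infer,
    )

    levels = hierarchy_mod.bfs_levels(report.final_pairs)
    locations = hierarchy_mod.locate_candidates(levels, report.final_tfs)

    summary = {
        "seed": cfg.seed,
        "n_random": cfg.n_random,
        "gcp_alpha": cfg.gcp_alpha,
        "pc_alpha": cfg.pc_alpha,
        "fdr": cfg.fdr,
        "grubbs_alpha": cfg.grubbs_alpha,
        "n_networks": len(collection),
        "signature_sizes": {p: signatures[p].size for p in PERIODS},
        "n_active_networks": {
            f"{s}_{p}": sum(r.significant for r in screen_results[(s, p)])
            for s, p in CELLS
        },
        "n_pairs_screening": {
            f"{s}_{p}": len(pairs_screen[(s, p)].pairs) for s, p in CELLS
        },
        "n_pairs_inference": {
            f"{s}_{p}": len(pairs_infer[(s, p)].pairs) for s, p in CELLS
        },
        "n_specificity_screening": len(spec_screen),
        "n_coverage_screening": len(cov_screen),
        "n_specificity_inference": len(spec_infer),
        "n_coverage_inference": len(cov_infer),
        "overlap_matrix": report.overlap_matrix.tolist(),
        "final_tfs": sorted(report.final_tfs),
        "n_final_pairs": len(report.final_pairs),
        "n_final_unique_genes": len(report.final_unique_genes),
    }
    return PipelineResult(
        report=report,
        signatures=signatures,
        screen_results=screen_results,
        skeletons=skeletons,
        pairs_screening=pairs_screen,
        pairs_inference=pairs_infer,
        hierarchy_levels=levels,
        candidate_locations=locations,
        summary=summary,
    )


def run_all(
    artifacts_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Load artifacts from disk, run the pipeline, persist every output."""
    cfg = config or RunConfig()
    art = Path(artifacts_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    collection = iodata.read_network_collection(
        art / "gene_sets.gmt", art / "relations.tsv", art / "tfs.txt"
    )
    dataset = iodata.read_expression(
        art / "expression.tsv", art / "samples.tsv"
    )
    tf_list = iodata.read_tf_list(art / "tfs.txt")

    result = run_pipeline(collection, dataset, tf_list, cfg)

    for p in PERIODS:
        signature.write_signature(
            result.signatures[p], out / f"signature_{p}.tsv"
        )
    for (s, p), res in result.screen_results.items():
        iodata.write_gcp_table(res, out / f"gcp_{s}_{p}.tsv")
    if result.skeletons:
        iodata.write_skeletons(result.skeletons, out / "skeletons")
    iodata.write_report(result.report, out, summary=result.summary)
    result.candidate_locations.to_csv(
        out / "hierarchy.tsv", sep="\t", index=False
    )
    return result


def recovery_experiment(
    scenario: synthdata.Scenario | None = None,
    n_seeds: int = 10,
    base_seed: int = 0,
    config: RunConfig | None = None,
) -> dict:
    """Planted-MR parameter-recovery harness.

    Runs the full pipeline on ``n_seeds`` independent draws of the scenario
    and pools true/false positives over runs: recall is pooled TP over
    planted, precision pooled TP over reported.  Child seeds are
    ``base_seed * 1000 + i`` (kept below 2**31).
    """
    scenario = scenario or synthdata.Scenario()
    truth = {s.casefold() for s in synthdata.end_to_end_truth(scenario)}
    tp = fp = fn = 0
    per_seed = []
    for i in range(n_seeds):
        child = (base_seed * 1000 + i) % (2**31)
        sc = dataclasses.replace(scenario, seed=child)
        collection = synthdata.make_reference_collection(sc)
        dataset = synthdata.simulate_expression(sc, collection)
        cfg = dataclasses.replace(
            config or RunConfig(n_random=200, pc_max_order=2), seed=child
        )
        result = run_pipeline(
            list(collection.networks), dataset, list(collection.tf_list), cfg
        )
        found = {t.casefold() for t in result.report.final_tfs}
        tp += len(found & truth)
        fp += len(found - truth)
        fn += len(truth - found)
        per_seed.append(sorted(found))
        log.info("seed %d: found %s", child, sorted(found))
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    precision = tp / (tp + fp) if (tp + fp) else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "per_seed": per_seed,
        "n_seeds": n_seeds,
    }
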