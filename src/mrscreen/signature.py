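"""Per-period expression signatures: case-vs-control differential genes.

The expression signature of a period is the ensemble of genes whose
expression differs between the case and control strains at a false
discovery rate below the threshold (default 0.05).  Each gene is tested
with a Welch two-sample t test on the period's pooled samples (a period
pools its constituent time points) and the p-values are adjusted by the
Benjamini-Hochberg step-up procedure.  Signatures are computed on the raw
(unstandardized) values; standardization is a screening-internal concern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iodata import ExpressionDataset, canon

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureResult:
    period: str
    table: pd.DataFrame  # gene, p_value, q_value, case_mean, control_mean
    signature_genes: frozenset[str]  # canonical symbols with q < threshold
    threshold: float

    @property
    def size(self) -> int:
        return len(self.signature_genes)

    def __contains__(self, gene: str) -> bool:
        return canon(gene) in self.signature_genes


def gene_test(case_values: np.ndarray, control_values: np.ndarray) -> float:
    """Welch two-sample t-test p-value for one gene.

    Degenerate input (zero variance in both groups) yields p = 1 for equal
    means — no evidence either way from constant data — and p = 0 for a
    deterministic mean difference; both cases are logged.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per group")
    if a.var() == 0.0 and b.var() == 0.0:
        equal = np.isclose(a.mean(), b.mean())
        log.info("zero variance in both groups; p=%s", 1.0 if equal else 0.0)
        return 1.0 if equal else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(p)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_signature(
    dataset: ExpressionDataset, period: str, threshold: float = 0.05
) -> SignatureResult:
    """Signature of one period over all genes of the dataset.

    Both strains must be present in the period; the threshold applies to
    the BH-adjusted q-values.  ``threshold = 0`` yields an empty signature.
    """
    view = dataset.period_view(period)
    case_cols = [
        k for k, s in enumerate(view.sample_ids) if view.strain_of(s) == "case"
    ]
    control_cols = [
        k for k, s in enumerate(view.sample_ids)
        if view.strain_of(s) == "control"
    ]
    if not case_cols or not control_cols:
        raise ValueError(f"period {period!r} lacks one of the strains")

    case = view.values[:, case_cols]
    control = view.values[:, control_cols]

    # vectorized Welch test; fall back to the scalar path for degenerate rows
    res = stats.ttest_ind(case, control, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    for i in np.flatnonzero(degenerate):
        p[i] = gene_test(case[i], control[i])

    q = bh_adjust(p)
    genes_sorted_view = list(dataset.gene_ids)
    table = pd.DataFrame(
        {
            "gene": genes_sorted_view,
            "p_value": p,
            "q_value": q,
            "case_mean": case.mean(axis=1),
            "control_mean": control.mean(axis=1),
        }
    )
    signature = frozenset(
        canon(g) for g, qv in zip(genes_sorted_view, q) if qv < threshold
    )
    log.info("period %s: signature of %d genes", period, len(signature))
    return SignatureResult(
        period=period,
        table=table,
        signature_genes=signature,
        threshold=threshold,
    )


def write_signature(result: SignatureResult, path) -> None:
    out = result.table.copy()
    out["in_signature"] = [
        canon(g) in result.signature_genes for g in out["gene"]
    ]
    out.to_csv(path, sep="\t", index=False)
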