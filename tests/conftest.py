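import logging

import numpy as np
import pytest

from mrscreen.iodata import CELLS, ExpressionDataset, RegulatoryNetwork

logging.getLogger("mrscreen").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def make_dataset(values, genes=None, strain="case", period="P1"):
    """Small single-cell dataset from a raw matrix (genes x samples)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = [f"s{k + 1}" for k in range(values.shape[1])]
    return ExpressionDataset(
        gene_ids=tuple(genes),
        sample_ids=tuple(samples),
        values=values,
        sample_meta={s: (strain, period) for s in samples},
    )


def make_six_cell_dataset(rng, genes, n_per_cell=6, tweak=None):
    """Dataset covering all six cells; ``tweak(strain, period, block)`` may
    modify each cell's genes x samples block in place."""
    blocks, sample_ids, meta = [], [], {}
    for strain, period in CELLS:
        block = rng.normal(size=(len(genes), n_per_cell))
        if tweak is not None:
            tweak(strain, period, block)
        blocks.append(block)
        for k in range(n_per_cell):
            sid = f"{strain}_{period}_{k}"
            sample_ids.append(sid)
            meta[sid] = (strain, period)
    return ExpressionDataset(
        gene_ids=tuple(genes),
        sample_ids=tuple(sample_ids),
        values=np.concatenate(blocks, axis=1),
        sample_meta=meta,
    )


@pytest.fixture
def chain_network():
    return RegulatoryNetwork(
        network_id="chain",
        name="chain",
        edges=frozenset({("A", "B"), ("B", "C")}),
    )
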