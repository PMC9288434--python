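import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hemorank.core_io import ExpressionBundle, PipelineConfig, SeedPanel
from hemorank.preprocess import lognormalize


def make_bundle(counts, gene_ids=None, tissues=None, populations=None,
                normalized=False):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    cell_ids = [f"c{i}" for i in range(n_cells)]
    tissues = tissues or ["t0"] * n_cells
    populations = populations or ["endothelial"] * n_cells
    meta = pd.DataFrame({"tissue": tissues, "population": populations,
                         "dataset": "synthetic"},
                        index=pd.Index(cell_ids, name="cell_id"))
    b = ExpressionBundle(counts=sp.csr_matrix(counts), gene_ids=np.array(gene_ids, dtype=object),
                         cell_ids=np.array(cell_ids, dtype=object), cell_meta=meta)
    if normalized:
        b = lognormalize(b)
    return b


@pytest.fixture
def toy_bundle():
    """4 cells x 5 genes with simple structure."""
    counts = np.array([
        [5, 0, 1, 0, 2],
        [0, 3, 0, 0, 1],
        [2, 2, 2, 0, 2],
        [0, 0, 0, 0, 4],
    ])
    return make_bundle(counts)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(rng_seed=0)


@pytest.fixture(scope="session")
def panel():
    return SeedPanel()
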