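import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tumortalk import CountMatrix


@pytest.fixture
def matrix_factory():
    """Build small CountMatrix objects from dense arrays."""

    def make(counts, genes=None, samples=None, conditions=None, mito=()):
        counts = np.asarray(counts)
        genes = genes or [f"g{i}" for i in range(counts.shape[0])]
        cells = [f"c{i}" for i in range(counts.shape[1])]
        meta = pd.DataFrame(
            {
                "sample": samples or ["S1"] * len(cells),
                "condition": conditions or ["A"] * len(cells),
            },
            index=cells,
        )
        return CountMatrix(
            genes=genes,
            cells=cells,
            counts=sp.csr_matrix(counts),
            cell_meta=meta,
            mito_genes=frozenset(mito),
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
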