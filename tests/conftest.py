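import numpy as np
import pandas as pd
import pytest

from atlasguide import CellAnnotation, CountMatrix, normalize_cpm


def make_counts(values, gene_ids=None, cell_ids=None, **kwargs) -> CountMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    cell_ids = cell_ids or [f"c{i}" for i in range(values.shape[1])]
    return CountMatrix(pd.Index(gene_ids), pd.Index(cell_ids), values, **kwargs)


def random_counts(rng, n_genes=20, n_cells=10, **kwargs) -> CountMatrix:
    return make_counts(rng.poisson(30.0, size=(n_genes, n_cells)) + 1.0, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_atlas(rng):
    """CPM-normalized 30-gene atlas of 3 types x 6 cells with markers."""
    n_genes, types = 30, ["alpha", "beta", "delta"]
    cells, labels, cols = [], [], []
    for t_idx, t in enumerate(types):
        base = rng.uniform(5, 20, size=n_genes)
        base[t_idx * 5:(t_idx + 1) * 5] *= 30  # planted markers
        for j in range(6):
            cols.append(rng.poisson(base * 20))
            cells.append(f"{t}_{j}")
            labels.append(t)
    m = make_counts(np.array(cols, dtype=float).T, cell_ids=cells)
    ann = CellAnnotation(pd.Series(labels, index=cells))
    return normalize_cpm(m), ann
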