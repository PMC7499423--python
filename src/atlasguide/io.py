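"""Readers and writers for count matrices and annotations.

Supported formats:

* dense CSV/TSV, genes as rows, header row of cell ids, first column of
  gene ids (transposed import available via ``orientation="cells_by_genes"``)
* MatrixMarket ``.mtx`` triplet plus sidecar gene/cell id lists
  (one id per line)
* AnnData ``.h5ad`` (read-only; raw counts layer preferred when present)
* Loom (read-only, via h5py; Loom stores genes as rows)

Annotations are two-column CSV/TSV files (cell_id, cell_type) with a
header row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .core import CellAnnotation, CountMatrix, DataValidationError


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_counts_csv(path, orientation: str = "genes_by_cells") -> CountMatrix:
    """Read a dense CSV/TSV count table.

    ``orientation`` declares the layout on disk; the returned matrix is
    always genes x cells.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "cells_by_genes":
        df = df.T
    elif orientation != "genes_by_cells":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix.from_frame(df)


def write_counts_csv(m: CountMatrix, path) -> None:
    m.to_frame().to_csv(path, sep=_sep_for(path))


def read_counts_mtx(path, genes_path=None, cells_path=None) -> CountMatrix:
    """Read a MatrixMarket triplet with gene/cell id sidecar files.

    Sidecars default to ``<stem>.genes.txt`` / ``<stem>.cells.txt`` next
    to the matrix file. The matrix on disk is genes x cells.
    """
    stem = str(path)
    for suffix in (".mtx",):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    genes_path = genes_path or stem + ".genes.txt"
    cells_path = cells_path or stem + ".cells.txt"
    for p in (genes_path, cells_path):
        if not os.path.exists(p):
            raise FileNotFoundError(f"missing sidecar id list: {p}")
    genes = pd.Index([ln.strip() for ln in open(genes_path) if ln.strip()])
    cells = pd.Index([ln.strip() for ln in open(cells_path) if ln.strip()])
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    return CountMatrix(genes, cells, np.asarray(mat, dtype=np.float64))


def write_counts_mtx(m: CountMatrix, path) -> None:
    stem = str(path)
    if stem.endswith(".mtx"):
        stem = stem[:-4]
    scipy.io.mmwrite(stem + ".mtx", scipy.sparse.coo_matrix(m.values))
    with open(stem + ".genes.txt", "w") as fh:
        fh.write("\n".join(map(str, m.gene_ids)) + "\n")
    with open(stem + ".cells.txt", "w") as fh:
        fh.write("\n".join(map(str, m.cell_ids)) + "\n")


def read_counts_h5ad(path) -> CountMatrix:
    """Read an AnnData container, preferring the raw counts layer.

    AnnData is cells x genes; the result is transposed to genes x cells.
    Preference order: ``layers['counts']``, ``.raw.X``, ``.X``.
    """
    import anndata

    adata = anndata.read_h5ad(path)
    if "counts" in adata.layers:
        x, var_names = adata.layers["counts"], adata.var_names
    elif adata.raw is not None:
        x, var_names = adata.raw.X, adata.raw.var_names
    else:
        x, var_names = adata.X, adata.var_names
    if scipy.sparse.issparse(x):
        x = x.toarray()
    return CountMatrix(
        pd.Index(var_names.astype(str)),
        pd.Index(adata.obs_names.astype(str)),
        np.asarray(x, dtype=np.float64).T,
    )


def read_counts_loom(path) -> CountMatrix:
    """Read a Loom file (HDF5 layout; genes are rows by convention)."""
    import h5py

    def _ids(group, preferred):
        for key in preferred:
            if key in group:
                return [v.decode() if isinstance(v, bytes) else str(v)
                        for v in group[key][:]]
        raise DataValidationError(
            f"loom file lacks an id attribute among {preferred}"
        )

    with h5py.File(path, "r") as fh:
        matrix = np.asarray(fh["matrix"][:], dtype=np.float64)
        genes = _ids(fh["row_attrs"], ("Gene", "GeneName", "var_names", "Accession"))
        cells = _ids(fh["col_attrs"], ("CellID", "obs_names", "Cell"))
    return CountMatrix(pd.Index(genes), pd.Index(cells), matrix)


_READERS = {
    ".csv": read_counts_csv,
    ".tsv": read_counts_csv,
    ".txt": read_counts_csv,
    ".mtx": read_counts_mtx,
    ".h5ad": read_counts_h5ad,
    ".loom": read_counts_loom,
}


def read_counts(path, **kwargs) -> CountMatrix:
    """Dispatch on file extension to the matching reader."""
    ext = os.path.splitext(str(path))[1].lower()
    try:
        reader = _READERS[ext]
    except KeyError:
        raise ValueError(
            f"unsupported count format {ext!r}; expected one of {sorted(_READERS)}"
        ) from None
    return reader(path, **kwargs)


def read_annotation(path) -> CellAnnotation:
    """Read a two-column (cell_id, cell_type) table with header."""
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] < 2:
        raise DataValidationError(
            f"annotation file needs two columns (cell_id, cell_type), got {df.shape[1]}"
        )
    return CellAnnotation(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values))


def write_annotation(ann: CellAnnotation, path) -> None:
    pd.DataFrame(
        {"cell_id": ann.labels.index, "cell_type": ann.labels.values}
    ).to_csv(path, sep=_sep_for(path), index=False)
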