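"""Core containers and preprocessing for gene-expression count tables.

The central object is :class:`CountMatrix`, a genes x cells table of
non-negative expression values. All downstream steps (landmark
compression, feature selection, graph construction) operate on
counts-per-million (CPM) normalized matrices; raw counts are only used
for QC filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CPM_TOTAL = 1_000_000.0

#: labels treated as ambiguous annotations unless the caller overrides
DEFAULT_AMBIGUOUS_LABELS = frozenset({"unknown", "hybrid"})


class DataValidationError(ValueError):
    """Raised when an input matrix or annotation violates its contract."""


@dataclass
class CountMatrix:
    """Genes x cells expression matrix with identifiers.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    cell_ids
        Unique cell identifiers, one per matrix column.
    values
        Dense ``(n_genes, n_cells)`` array of non-negative values.
    normalized
        Whether counts-per-million normalization has been applied. When
        True (and ``log_transformed`` is False) every column with a
        nonzero total sums to 1e6.
    log_transformed
        Whether the zero-preserving shifted log10 has been applied.
    """

    gene_ids: pd.Index
    cell_ids: pd.Index
    values: np.ndarray
    normalized: bool = False
    log_transformed: bool = False
    #: True once rows were subset after normalization, which voids the
    #: column-sum invariant without changing the per-gene CPM scale
    gene_subset: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        self.cell_ids = pd.Index(self.cell_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D genes x cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        for name, idx in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if idx.has_duplicates:
                dups = idx[idx.duplicated()].unique().tolist()
                raise DataValidationError(f"duplicate {name} ids: {dups[:10]}")
        if not np.isfinite(self.values).all():
            raise DataValidationError("values contain NaN or infinite entries")
        if (self.values < 0).any():
            raise DataValidationError("values contain negative entries")
        if self.normalized and not self.log_transformed and not self.gene_subset:
            totals = self.values.sum(axis=0)
            nonzero = totals > 0
            if nonzero.any():
                rel = np.abs(totals[nonzero] - CPM_TOTAL) / CPM_TOTAL
                if (rel > 1e-6).any():
                    raise DataValidationError(
                        "normalized flag set but column totals deviate from 1e6"
                    )

    # -- convenience -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def column_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kwargs) -> "CountMatrix":
        return cls(df.index, df.columns, df.to_numpy(dtype=np.float64), **kwargs)

    def subset_genes(self, genes) -> "CountMatrix":
        indexer = self.gene_ids.get_indexer(pd.Index(genes))
        if (indexer < 0).any():
            missing = [g for g, i in zip(genes, indexer) if i < 0]
            raise KeyError(f"genes not present: {missing[:10]}")
        return replace(self, gene_ids=pd.Index(genes, dtype=object),
                       values=self.values[indexer, :],
                       gene_subset=self.gene_subset or self.normalized)

    def subset_cells(self, cells) -> "CountMatrix":
        indexer = self.cell_ids.get_indexer(pd.Index(cells))
        if (indexer < 0).any():
            missing = [c for c, i in zip(cells, indexer) if i < 0]
            raise KeyError(f"cells not present: {missing[:10]}")
        return replace(self, cell_ids=pd.Index(cells, dtype=object),
                       values=self.values[:, indexer])


@dataclass
class CellAnnotation:
    """Mapping cell_id -> cell-type label (non-empty strings)."""

    labels: pd.Series
    ambiguous_labels: frozenset = field(default=DEFAULT_AMBIGUOUS_LABELS)

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, dtype=object)
        if self.labels.index.has_duplicates:
            dups = self.labels.index[self.labels.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate annotated cell ids: {dups[:10]}")
        if self.labels.isna().any() or (self.labels.astype(str) == "").any():
            raise DataValidationError("empty or missing cell-type labels")
        self.ambiguous_labels = frozenset(self.ambiguous_labels)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def cell_ids(self) -> pd.Index:
        return self.labels.index

    def cell_types(self) -> list:
        """Distinct labels in first-appearance order."""
        return list(dict.fromkeys(self.labels))

    def is_ambiguous(self) -> pd.Series:
        return self.labels.isin(self.ambiguous_labels)


# ---------------------------------------------------------------------
# operations


def intersect_genes(a: CountMatrix, b: CountMatrix) -> tuple[CountMatrix, CountMatrix]:
    """Restrict both matrices to their shared genes, in ``a``'s order.

    Only genes present in both datasets are retained; cells are
    untouched. Raises if the two gene universes are disjoint.
    """
    common = a.gene_ids[a.gene_ids.isin(b.gene_ids)]
    if len(common) == 0:
        raise DataValidationError(
            "empty gene intersection between datasets "
            f"(first has {a.n_genes} genes e.g. {list(a.gene_ids[:3])}, "
            f"second has {b.n_genes} genes e.g. {list(b.gene_ids[:3])})"
        )
    return a.subset_genes(common), b.subset_genes(common)


def normalize_cpm(m: CountMatrix, force: bool = False) -> CountMatrix:
    """Scale each cell's column to one million total counts.

    All-zero cells are left all-zero and reported via a warning.
    ``force`` disables the double-normalization guard (the operation is
    then idempotent in effect).
    """
    if m.normalized and not force:
        raise DataValidationError("matrix is already CPM-normalized")
    totals = m.column_totals()
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero cell(s) left unnormalized: "
            f"{list(m.cell_ids[zero][:10])}",
            stacklevel=2,
        )
    scale = np.divide(CPM_TOTAL, totals, out=np.zeros_like(totals), where=~zero)
    return replace(m, values=m.values * scale[np.newaxis, :], normalized=True)


def filter_cells(m: CountMatrix, min_total_counts: float) -> CountMatrix:
    """Drop cells whose total raw counts fall below ``min_total_counts``.

    Boundary semantics follow "less than": a cell exactly at the
    threshold is kept. Order of surviving cells is preserved.
    """
    if m.normalized:
        raise DataValidationError("QC filtering operates on raw counts")
    if min_total_counts < 0:
        raise ValueError("min_total_counts must be non-negative")
    keep = m.column_totals() >= min_total_counts
    if not keep.any():
        raise DataValidationError(
            f"no cells pass QC at min_total_counts={min_total_counts}"
        )
    return m.subset_cells(m.cell_ids[keep])


def log_shift(values: np.ndarray, pseudocount: float) -> np.ndarray:
    """Zero-preserving shifted log10: x -> log10(x + pc) - log10(pc)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return np.log10(values + pseudocount) - np.log10(pseudocount)


def log_transform(m: CountMatrix, pseudocount: float = 0.1) -> CountMatrix:
    """Apply the zero-preserving shifted log10 elementwise.

    Maps 0 to 0, keeps values non-negative and is strictly monotone, so
    sparsity structure and within-gene rank orders are preserved.
    """
    if not m.normalized:
        raise DataValidationError("log transform expects a CPM-normalized matrix")
    if m.log_transformed:
        raise DataValidationError("matrix is already log-transformed")
    return replace(m, values=log_shift(m.values, pseudocount), log_transformed=True)


def drop_zero_cells(m: CountMatrix) -> CountMatrix:
    """Remove all-zero cells (e.g. after gene intersection), warning once."""
    keep = m.column_totals() > 0
    if keep.all():
        return m
    warnings.warn(
        f"dropping {int((~keep).sum())} all-zero cell(s): "
        f"{list(m.cell_ids[~keep][:10])}",
        stacklevel=2,
    )
    if not keep.any():
        raise DataValidationError("all cells are zero after gene intersection")
    return m.subset_cells(m.cell_ids[keep])
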