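"""Atlas landmark compression: per-type averages or labeled subsamples.

An annotated atlas with hundreds of thousands of cells is compressed to
a handful of *landmarks* per cell type: either the arithmetic average of
the CPM-normalized profiles of each type, or a small uniform random
subsample of its cells. Both representations grow with the number of
cell types, not the number of atlas cells, which is what makes guidance
by very large atlases tractable.

Landmarks serialize to a two-file bundle: ``<name>.landmarks.tsv``
(types or cells x genes matrix) plus ``<name>.landmarks.json``
(labels, per-type cell counts, format metadata).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_AMBIGUOUS_LABELS,
    CellAnnotation,
    CountMatrix,
    DataValidationError,
)

_FORMAT_VERSION = 1
#: fixed-width value format so the TSV payload size depends only on shape
_VALUE_FMT = "%.6e"


@dataclass
class AtlasAverages:
    """Per-type arithmetic averages of CPM-normalized expression."""

    cell_types: list
    gene_ids: pd.Index
    means: np.ndarray  # types x genes
    n_cells: np.ndarray  # per-type cell counts

    def __post_init__(self) -> None:
        self.cell_types = list(self.cell_types)
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.n_cells = np.asarray(self.n_cells, dtype=np.int64)
        if len(set(self.cell_types)) != len(self.cell_types):
            raise DataValidationError("duplicate cell types in averages")
        if self.means.shape != (len(self.cell_types), len(self.gene_ids)):
            raise DataValidationError("averages matrix shape mismatch")
        if (self.means < 0).any():
            raise DataValidationError("negative average expression")
        if (self.n_cells < 1).any():
            raise DataValidationError("every type needs at least one cell")

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def subset_genes(self, genes) -> "AtlasAverages":
        indexer = self.gene_ids.get_indexer(pd.Index(genes))
        if (indexer < 0).any():
            missing = [g for g, i in zip(genes, indexer) if i < 0]
            raise KeyError(f"genes not present in landmarks: {missing[:10]}")
        return AtlasAverages(self.cell_types, pd.Index(genes, dtype=object),
                             self.means[:, indexer], self.n_cells)


@dataclass
class AtlasSubsample:
    """A small labeled subsample of atlas cells (CPM-normalized)."""

    matrix: CountMatrix
    annotation: CellAnnotation
    n_per_type: int

    def __post_init__(self) -> None:
        if set(self.matrix.cell_ids) != set(self.annotation.cell_ids):
            raise DataValidationError("subsample cells and annotation disagree")
        if self.annotation.is_ambiguous().any():
            raise DataValidationError("subsample contains ambiguous labels")

    @property
    def cell_types(self) -> list:
        return self.annotation.cell_types()

    @property
    def gene_ids(self) -> pd.Index:
        return self.matrix.gene_ids

    def subset_genes(self, genes) -> "AtlasSubsample":
        return AtlasSubsample(self.matrix.subset_genes(genes),
                              self.annotation, self.n_per_type)


Landmarks = AtlasAverages | AtlasSubsample


def exclude_ambiguous_types(
    ann: CellAnnotation, blacklist=DEFAULT_AMBIGUOUS_LABELS
) -> CellAnnotation:
    """Drop cells whose label is in the ambiguity blacklist.

    Returns the filtered annotation; removed counts per label are
    reported via a warning.
    """
    blacklist = frozenset(blacklist)
    mask = ann.labels.isin(blacklist)
    if mask.any():
        removed = ann.labels[mask].value_counts().to_dict()
        warnings.warn(f"excluded ambiguous cells per label: {removed}", stacklevel=2)
    if mask.all():
        warnings.warn("all cells carried blacklisted labels", stacklevel=2)
    return CellAnnotation(ann.labels[~mask], ambiguous_labels=blacklist)


def _check_atlas_inputs(atlas: CountMatrix, ann: CellAnnotation) -> pd.Series:
    if not atlas.normalized:
        raise DataValidationError("atlas must be CPM-normalized first")
    missing = atlas.cell_ids.difference(ann.cell_ids)
    if len(missing):
        raise DataValidationError(
            f"{len(missing)} atlas cell(s) lack annotations, e.g. {list(missing[:5])}"
        )
    labels = ann.labels.reindex(atlas.cell_ids)
    if labels.isin(ann.ambiguous_labels).any():
        raise DataValidationError(
            "ambiguous labels present; run exclude_ambiguous_types first"
        )
    return labels


def compute_averages(atlas: CountMatrix, ann: CellAnnotation) -> AtlasAverages:
    """Arithmetic mean of the normalized counts for each cell type."""
    labels = _check_atlas_inputs(atlas, ann)
    types = list(dict.fromkeys(labels))
    means = np.empty((len(types), atlas.n_genes))
    n_cells = np.empty(len(types), dtype=np.int64)
    for i, t in enumerate(types):
        cols = np.flatnonzero((labels == t).to_numpy())
        means[i] = atlas.values[:, cols].mean(axis=1)
        n_cells[i] = len(cols)
    return AtlasAverages(types, atlas.gene_ids, means, n_cells)


def subsample_atlas(
    atlas: CountMatrix, ann: CellAnnotation, n_per_type: int, seed: int
) -> AtlasSubsample:
    """Uniform random subsample without replacement, per cell type.

    Each type contributes ``min(n_per_type, available)`` cells; the
    selection is deterministic given ``seed``.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be at least 1")
    labels = _check_atlas_inputs(atlas, ann)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for t in dict.fromkeys(labels):
        cells = atlas.cell_ids[(labels == t).to_numpy()]
        if len(cells) > n_per_type:
            cells = pd.Index(sorted(rng.choice(cells, n_per_type, replace=False)))
        chosen.extend(cells)
    sub = atlas.subset_cells(chosen)
    sub_ann = CellAnnotation(labels.reindex(chosen),
                             ambiguous_labels=ann.ambiguous_labels)
    return AtlasSubsample(sub, sub_ann, n_per_type)


# ---------------------------------------------------------------------
# serialization


def _bundle_paths(path) -> tuple[str, str]:
    stem = str(path)
    for suffix in (".landmarks.tsv", ".landmarks.json", ".landmarks"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return stem + ".landmarks.tsv", stem + ".landmarks.json"


def save_landmarks(landmarks: Landmarks, path) -> tuple[str, str]:
    """Write a landmark bundle; returns the (tsv, json) paths."""
    tsv_path, json_path = _bundle_paths(path)
    if isinstance(landmarks, AtlasAverages):
        df = pd.DataFrame(landmarks.means, index=landmarks.cell_types,
                          columns=landmarks.gene_ids)
        meta = {
            "format_version": _FORMAT_VERSION,
            "kind": "averages",
            "cell_types": landmarks.cell_types,
            "n_cells": landmarks.n_cells.tolist(),
        }
    elif isinstance(landmarks, AtlasSubsample):
        df = landmarks.matrix.to_frame().T  # cells x genes
        meta = {
            "format_version": _FORMAT_VERSION,
            "kind": "subsample",
            "cell_labels": {str(c): str(l)
                            for c, l in landmarks.annotation.labels.items()},
            "n_per_type": landmarks.n_per_type,
            "blacklist": sorted(landmarks.annotation.ambiguous_labels),
        }
    else:
        raise TypeError(f"cannot serialize {type(landmarks).__name__}")
    df.to_csv(tsv_path, sep="\t", float_format=_VALUE_FMT)
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=1)
        fh.write("\n")
    return tsv_path, json_path


def load_landmarks(path) -> Landmarks:
    """Load a landmark bundle written by :func:`save_landmarks`."""
    tsv_path, json_path = _bundle_paths(path)
    with open(json_path) as fh:
        meta = json.load(fh)
    kind = meta.get("kind")
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if kind == "averages":
        for field_name in ("cell_types", "n_cells"):
            if field_name not in meta:
                raise DataValidationError(
                    f"landmark bundle missing field {field_name!r}"
                )
        return AtlasAverages(meta["cell_types"], df.columns,
                             df.to_numpy(), meta["n_cells"])
    if kind == "subsample":
        for field_name in ("cell_labels", "n_per_type"):
            if field_name not in meta:
                raise DataValidationError(
                    f"landmark bundle missing field {field_name!r}"
                )
        matrix = CountMatrix(df.columns, df.index, df.to_numpy().T, normalized=True)
        ann = CellAnnotation(
            pd.Series(meta["cell_labels"]).reindex(df.index),
            ambiguous_labels=frozenset(meta.get("blacklist", [])),
        )
        return AtlasSubsample(matrix, ann, int(meta["n_per_type"]))
    raise DataValidationError(f"landmark bundle missing or unknown kind: {kind!r}")
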