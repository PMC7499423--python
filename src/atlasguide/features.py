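"""Informative-gene selection for the joint atlas/new-data analysis.

Two complementary sources feed the feature set:

* **markers** — for each atlas cell type, genes most upregulated in
  that type relative to the *strongest* other type (log10 ratio with a
  pseudocount); a marker must beat every other type, not just their
  average.
* **overdispersed genes** — genes with the highest Fano factor
  (variance/mean of CPM values) across the new cells; these capture
  structure, such as neoplastic populations, absent from the atlas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountMatrix, DataValidationError
from .landmarks import AtlasAverages, AtlasSubsample, Landmarks, compute_averages


@dataclass
class FeatureParams:
    """Knobs of feature selection.

    n_markers_per_type
        Markers kept for each atlas cell type (>= 1).
    n_overdispersed
        Genes kept by Fano-factor ranking on the new dataset.
    pseudocount
        Additive stabilizer for the log fold-change marker score, in
        CPM units.
    """

    n_markers_per_type: int = 30
    n_overdispersed: int = 500
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.n_markers_per_type < 1:
            raise ValueError("n_markers_per_type must be >= 1")
        if self.n_overdispersed < 0:
            raise ValueError("n_overdispersed must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class FeatureSet:
    """Ordered unique gene list with per-gene provenance.

    Provenance is ``"marker:<type>"`` (first type that selected it),
    ``"overdispersed"`` or ``"both"``.
    """

    genes: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise DataValidationError("duplicate genes in feature set")
        if not self.genes:
            raise DataValidationError("empty feature set")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes,
             "provenance": [self.provenance.get(g, "") for g in self.genes]}
        )


def _top_by_score(gene_ids: pd.Index, scores: np.ndarray, n: int) -> list:
    """Top-n gene ids by descending score, ties by lexicographic id."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], str(gene_ids[i])))
    return [gene_ids[i] for i in order[:n]]


def marker_scores(averages: AtlasAverages, pseudocount: float) -> np.ndarray:
    """types x genes matrix of upregulation scores.

    score[t, g] = log10(mean[t, g] + pc) - log10(max over other types + pc)
    """
    if averages.n_types < 2:
        raise DataValidationError(
            "marker selection needs at least two atlas cell types"
        )
    log_means = np.log10(averages.means + pseudocount)
    n_types = averages.n_types
    scores = np.empty_like(log_means)
    for t in range(n_types):
        others = np.delete(log_means, t, axis=0)
        scores[t] = log_means[t] - others.max(axis=0)
    return scores


def select_markers(landmarks: Landmarks, params: FeatureParams) -> dict:
    """Per-type top markers; returns ``{cell_type: [genes...]}``.

    For subsample landmarks the per-type averages of the subsample are
    used, so one marker definition serves both landmark modes.
    """
    if isinstance(landmarks, AtlasSubsample):
        averages = compute_averages(landmarks.matrix, landmarks.annotation)
    else:
        averages = landmarks
    scores = marker_scores(averages, params.pseudocount)
    return {
        t: _top_by_score(averages.gene_ids, scores[i], params.n_markers_per_type)
        for i, t in enumerate(averages.cell_types)
    }


def fano_factors(new_data: CountMatrix) -> np.ndarray:
    """Per-gene Fano factor (variance/mean) of CPM values.

    Genes with zero mean get score 0.
    """
    if not new_data.normalized:
        raise DataValidationError("overdispersion expects CPM-normalized data")
    if new_data.n_cells < 2:
        raise DataValidationError("overdispersion needs at least two cells")
    mean = new_data.values.mean(axis=1)
    var = new_data.values.var(axis=1)
    return np.divide(var, mean, out=np.zeros_like(mean), where=mean > 0)


def select_overdispersed(new_data: CountMatrix, n: int) -> list:
    """Top-n genes of the new dataset by Fano factor."""
    if n == 0:
        return []
    if n > new_data.n_genes:
        warnings.warn(
            f"requested {n} overdispersed genes but only {new_data.n_genes} exist; "
            "clamping", stacklevel=2,
        )
        n = new_data.n_genes
    return _top_by_score(new_data.gene_ids, fano_factors(new_data), n)


def build_feature_set(markers: dict, overdispersed: list) -> FeatureSet:
    """Union of marker and overdispersed genes with provenance.

    Order: markers in cell-type order (each type's list in rank order),
    then overdispersed genes by rank; duplicates kept once. A gene found
    by both routes gets provenance ``"both"``.
    """
    genes: list = []
    provenance: dict = {}
    for cell_type, marker_genes in markers.items():
        for g in marker_genes:
            if g not in provenance:
                genes.append(g)
                provenance[g] = f"marker:{cell_type}"
    for g in overdispersed:
        if g in provenance:
            if not provenance[g].startswith("overdispersed"):
                provenance[g] = "both"
        else:
            genes.append(g)
            provenance[g] = "overdispersed"
    if not genes:
        raise DataValidationError("feature selection produced an empty union")
    return FeatureSet(genes, provenance)


def select_features(
    landmarks: Landmarks, new_data: CountMatrix, params: FeatureParams
) -> FeatureSet:
    """Markers + overdispersed genes, restricted to the shared universe."""
    markers = select_markers(landmarks, params)
    over = select_overdispersed(new_data, params.n_overdispersed)
    fs = build_feature_set(markers, over)
    universe = set(new_data.gene_ids)
    missing = [g for g in fs.genes if g not in universe]
    if missing:
        raise DataValidationError(
            f"features absent from the new dataset: {missing[:10]}; "
            "intersect genes before selecting features"
        )
    return fs
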