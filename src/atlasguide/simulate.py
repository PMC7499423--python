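"""Synthetic paired (atlas, new dataset) generators with ground truth.

The simulator emulates the statistical structure the annotation method
assumes: discrete cell types distinguishable by upregulated marker
genes on a shared housekeeping background, negative-binomial counts,
and cell-to-cell library-size variation. Types flagged *novel*
contribute no atlas cells, so they must be discovered as novel
clusters. Ground-truth labels for the new cells are returned for
scoring.

Also provided: a random similarity-graph generator used to exercise
the constrained clustering in isolation, and partition scoring
(accuracy on known types, adjusted Rand index on novel-type cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .core import CellAnnotation, CountMatrix
from .graph import SimilarityGraph


@dataclass
class TypeSpec:
    """One simulated cell type.

    ``marker_genes`` are gene indices upregulated ``marker_effect``-fold
    in this type; a type with ``n_atlas_cells == 0`` is novel (absent
    from the atlas).
    """

    label: str
    n_atlas_cells: int
    n_new_cells: int
    marker_genes: tuple = ()
    marker_effect: float = 20.0


@dataclass
class SimulationParams:
    """Study conditions of a simulation run.

    n_genes
        Genes in both datasets (shared universe).
    types
        Type specifications; marker sets must be disjoint and at least
        one type must be present in the atlas.
    baseline_scale
        Scale of the exponential draw of baseline (housekeeping)
        expression propensities.
    dispersion
        Negative-binomial dispersion phi (variance = mu + phi mu^2),
        shared across genes.
    library_size_range
        Uniform range of per-cell total-count means.
    seed
        Seed for all randomness.
    """

    n_genes: int = 2000
    types: list = field(default_factory=list)
    baseline_scale: float = 1.0
    dispersion: float = 0.3
    library_size_range: tuple = (50_000, 200_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.types:
            raise ValueError("at least one type spec is required")
        if all(t.n_atlas_cells == 0 for t in self.types):
            raise ValueError("at least one type must be present in the atlas")
        seen: set = set()
        for t in self.types:
            markers = set(t.marker_genes)
            if markers & seen:
                raise ValueError("marker sets must be disjoint across types")
            if markers and max(markers) >= self.n_genes:
                raise ValueError("marker index beyond n_genes")
            if t.marker_effect < 1:
                raise ValueError("marker_effect must be >= 1")
            seen |= markers
        if self.dispersion <= 0 or self.baseline_scale <= 0:
            raise ValueError("dispersion and baseline_scale must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid library_size_range")

    @property
    def known_types(self) -> list:
        return [t.label for t in self.types if t.n_atlas_cells > 0]

    @property
    def novel_types(self) -> list:
        return [t.label for t in self.types if t.n_atlas_cells == 0]


def default_simulation(seed: int = 0, n_known: int = 5, n_novel: int = 2,
                       n_new_cells: int = 400, n_genes: int = 2000,
                       n_atlas_cells_per_type: int = 50,
                       markers_per_type: int = 10,
                       marker_effect: float = 20.0) -> SimulationParams:
    """Canonical benchmark conditions: 5 known + 2 novel types,
    400 new cells over 2,000 genes, 10 planted markers/type at 20x."""
    n_types = n_known + n_novel
    per_type = n_new_cells // n_types
    extra = n_new_cells - per_type * n_types
    types = []
    for i in range(n_types):
        novel = i >= n_known
        label = f"novel_type_{i - n_known + 1}" if novel else f"type_{i + 1}"
        types.append(TypeSpec(
            label=label,
            n_atlas_cells=0 if novel else n_atlas_cells_per_type,
            n_new_cells=per_type + (1 if i < extra else 0),
            marker_genes=tuple(range(i * markers_per_type,
                                     (i + 1) * markers_per_type)),
            marker_effect=marker_effect,
        ))
    return SimulationParams(n_genes=n_genes, types=types, seed=seed)


def _sample_counts(rng, propensities: np.ndarray, n_cells: int,
                   lib_range: tuple, dispersion: float) -> np.ndarray:
    """genes x cells negative-binomial counts for one cell type."""
    p = propensities / propensities.sum()
    lib_sizes = rng.uniform(lib_range[0], lib_range[1], size=n_cells)
    mu = p[:, None] * lib_sizes[None, :]
    r = 1.0 / dispersion  # NB shape so that var = mu + phi mu^2
    prob = r / (r + mu)
    return rng.negative_binomial(r, prob).astype(np.float64)


def simulate(params: SimulationParams):
    """Generate (atlas, atlas annotation, new data, truth labels).

    Counts are raw (not normalized); truth is a Series over new-cell
    ids. Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    baseline = rng.exponential(params.baseline_scale, size=params.n_genes) + 1e-3
    type_propensities = {}
    for t in params.types:
        prop = baseline.copy()
        if t.marker_genes:
            prop[list(t.marker_genes)] *= t.marker_effect
        type_propensities[t.label] = prop

    gene_ids = pd.Index([f"gene_{i:05d}" for i in range(params.n_genes)])
    atlas_blocks, atlas_cells, atlas_labels = [], [], []
    new_blocks, new_cells, truth = [], [], []
    for t in params.types:
        prop = type_propensities[t.label]
        if t.n_atlas_cells:
            atlas_blocks.append(_sample_counts(
                rng, prop, t.n_atlas_cells,
                params.library_size_range, params.dispersion))
            ids = [f"atlas_{t.label}_{j}" for j in range(t.n_atlas_cells)]
            atlas_cells += ids
            atlas_labels += [t.label] * t.n_atlas_cells
        if t.n_new_cells:
            new_blocks.append(_sample_counts(
                rng, prop, t.n_new_cells,
                params.library_size_range, params.dispersion))
            ids = [f"cell_{t.label}_{j}" for j in range(t.n_new_cells)]
            new_cells += ids
            truth += [t.label] * t.n_new_cells

    def stack(blocks):
        if not blocks:
            return np.empty((params.n_genes, 0))
        return np.concatenate(blocks, axis=1)

    atlas = CountMatrix(gene_ids, pd.Index(atlas_cells), stack(atlas_blocks))
    annotation = CellAnnotation(pd.Series(atlas_labels, index=atlas_cells,
                                          dtype=object))
    new_data = CountMatrix(gene_ids, pd.Index(new_cells), stack(new_blocks))
    truth = pd.Series(truth, index=new_cells, name="true_label")
    return atlas, annotation, new_data, truth


def score_assignment(predicted: pd.Series, truth: pd.Series,
                     novel_types=()) -> tuple[float, float]:
    """(accuracy on known-type cells, ARI on novel-type cells).

    ``novel_types`` lists the ground-truth labels absent from the
    atlas. Accuracy compares predicted labels to truth on cells whose
    true type is known; the adjusted Rand index compares predicted
    cluster ids to true novel-type ids on the remaining cells (label
    names need not match there — only the partition matters).
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth labels have different lengths")
    predicted = pd.Series(predicted).reindex(truth.index)
    if predicted.isna().any():
        raise ValueError("predicted labels missing for some cells")
    novel_types = set(novel_types)
    known_mask = ~truth.isin(novel_types)
    accuracy = float((predicted[known_mask] == truth[known_mask]).mean()) \
        if known_mask.any() else float("nan")
    if (~known_mask).any():
        ari = float(adjusted_rand_score(truth[~known_mask], predicted[~known_mask]))
    else:
        ari = float("nan")
    return accuracy, ari


def random_similarity_graph(seed: int, n_new: int = 40, n_labels: int = 3,
                            atlas_mode: str = "averages",
                            cells_per_label: int = 4,
                            edge_prob: float = 0.15,
                            atlas_edge_prob: float = 0.3,
                            new_node_size: int = 1) -> SimilarityGraph:
    """Random graph respecting the no-atlas-atlas-edge rule.

    ``atlas_mode`` "averages" yields one size-20 node per label;
    "subsample" yields ``cells_per_label`` size-1 nodes per label.
    Used for property testing of the constrained clustering.
    """
    rng = np.random.default_rng(seed)
    labels_list, sizes, is_atlas, ids = [], [], [], []
    for li in range(n_labels):
        lab = f"T{li}"
        reps = 1 if atlas_mode == "averages" else cells_per_label
        for r in range(reps):
            ids.append(f"{lab}_a{r}")
            labels_list.append(lab)
            sizes.append(20 if atlas_mode == "averages" else 1)
            is_atlas.append(True)
    for i in range(n_new):
        ids.append(f"n{i}")
        labels_list.append(None)
        sizes.append(new_node_size)
        is_atlas.append(False)
    n = len(ids)
    is_atlas = np.array(is_atlas)
    edges, weights = [], []
    for u in range(n):
        for v in range(u + 1, n):
            if is_atlas[u] and is_atlas[v]:
                continue
            prob = atlas_edge_prob if (is_atlas[u] or is_atlas[v]) else edge_prob
            if rng.random() < prob:
                edges.append((u, v))
                weights.append(rng.uniform(0.6, 1.0))
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    return SimilarityGraph(pd.Index(ids), is_atlas,
                           np.array(labels_list, dtype=object),
                           np.array(sizes, dtype=np.int64),
                           edges, np.array(weights, dtype=np.float64))
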