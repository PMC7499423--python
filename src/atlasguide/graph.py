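"""Merged-matrix construction, PCA and the cell similarity graph.

Atlas landmarks and the new cells are merged into a single features x
columns table, z-scored jointly, reduced by PCA, and connected by a
k-nearest-neighbor graph with one structural rule: edges join either
two new cells or a new cell with an atlas node — never two atlas nodes.
Atlas nodes therefore enter the graph only through the neighbor lists
of new cells, which is what lets the downstream clustering treat each
atlas type as a fixed reference population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .core import CountMatrix, DataValidationError, log_shift
from .features import FeatureSet
from .landmarks import AtlasAverages, AtlasSubsample, Landmarks


@dataclass
class GraphParams:
    """Dimensionality-reduction and graph-construction knobs.

    n_pcs
        Principal components retained (clamped to the usable rank).
    k_neighbors
        Neighbors per new cell.
    metric
        ``"correlation"`` (edge weight (1+r)/2, pruned below
        ``weight_threshold``) or ``"euclidean"`` (unit weights).
    atlas_node_size
        Node size given to each atlas-average node, so one average
        behaves in the clustering objective like a small population
        rather than a single cell. Subsampled atlas cells keep size 1.
    weight_threshold
        Minimum correlation-mode edge weight; weaker similarities are
        pruned.
    seed
        Seed for any randomized linear algebra.
    """

    n_pcs: int = 20
    k_neighbors: int = 10
    metric: str = "correlation"
    atlas_node_size: int = 20
    weight_threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 1 or self.k_neighbors < 1 or self.atlas_node_size < 1:
            raise ValueError("n_pcs, k_neighbors and atlas_node_size must be >= 1")
        if self.metric not in ("euclidean", "correlation"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class MergedMatrix:
    """Features x columns matrix of atlas nodes followed by new cells."""

    feature_ids: pd.Index
    column_ids: pd.Index
    values: np.ndarray
    is_atlas: np.ndarray
    labels: np.ndarray  # object array; None for new cells
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = pd.Index(self.feature_ids, dtype=object)
        self.column_ids = pd.Index(self.column_ids, dtype=object)
        if self.column_ids.has_duplicates:
            raise DataValidationError("duplicate column ids in merged matrix")
        n = len(self.column_ids)
        if self.values.shape != (len(self.feature_ids), n):
            raise DataValidationError("merged matrix shape mismatch")
        for label, atlas in zip(self.labels, self.is_atlas):
            if atlas and label is None:
                raise DataValidationError("atlas column without a label")

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)


@dataclass
class SimilarityGraph:
    """Weighted undirected graph over atlas nodes and new cells."""

    node_ids: pd.Index
    is_atlas: np.ndarray
    labels: np.ndarray
    sizes: np.ndarray
    edges: np.ndarray  # (E, 2) int, each row sorted, unique
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.node_ids = pd.Index(self.node_ids, dtype=object)
        self.is_atlas = np.asarray(self.is_atlas, dtype=bool)
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.edges[:, 0] == self.edges[:, 1]).any():
            raise DataValidationError("self-loop in similarity graph")
        both_atlas = self.is_atlas[self.edges[:, 0]] & self.is_atlas[self.edges[:, 1]]
        if both_atlas.any():
            raise DataValidationError("atlas-atlas edge in similarity graph")
        if len(self.weights) and not (
            (self.weights > 0).all() and (self.weights <= 1).all()
        ):
            raise DataValidationError("edge weights must lie in (0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def adjacency(self) -> list:
        """Neighbor list [(j, w), ...] per node."""
        adj: list = [[] for _ in range(self.n_nodes)]
        for (u, v), w in zip(self.edges, self.weights):
            adj[u].append((int(v), float(w)))
            adj[v].append((int(u), float(w)))
        return adj

    def isolated_new_nodes(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return np.flatnonzero((deg == 0) & ~self.is_atlas)

    def to_igraph(self):
        import igraph

        g = igraph.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges])
        g.es["weight"] = list(self.weights)
        return g

    # -- TSV dump / load (edge list + node table) --------------------
    def write_tsv(self, edges_path, nodes_path) -> None:
        pd.DataFrame(
            {"source": self.node_ids[self.edges[:, 0]],
             "target": self.node_ids[self.edges[:, 1]],
             "weight": self.weights}
        ).to_csv(edges_path, sep="\t", index=False)
        pd.DataFrame(
            {"id": self.node_ids,
             "is_atlas": self.is_atlas.astype(int),
             "label": ["" if l is None else l for l in self.labels],
             "size": self.sizes}
        ).to_csv(nodes_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, edges_path, nodes_path) -> "SimilarityGraph":
        nodes = pd.read_csv(nodes_path, sep="\t", dtype={"id": str, "label": str},
                            keep_default_na=False)
        edges = pd.read_csv(edges_path, sep="\t", dtype={"source": str, "target": str})
        ids = pd.Index(nodes["id"])
        lookup = {c: i for i, c in enumerate(ids)}
        e = np.array(
            [[lookup[s], lookup[t]] for s, t in zip(edges["source"], edges["target"])],
            dtype=np.int64,
        ).reshape(-1, 2)
        labels = np.array(
            [None if l == "" else l for l in nodes["label"]], dtype=object
        )
        return cls(ids, nodes["is_atlas"].to_numpy(dtype=bool), labels,
                   nodes["size"].to_numpy(dtype=np.int64), e,
                   edges["weight"].to_numpy(dtype=np.float64))


# ---------------------------------------------------------------------
# operations


def _dedupe_ids(atlas_ids: list, new_ids: pd.Index) -> list:
    """Suffix atlas column ids that collide with new-cell ids."""
    taken = set(new_ids)
    out = []
    for cid in atlas_ids:
        cid = str(cid)
        if cid in taken:
            k = 1
            while f"{cid}_atlas{k}" in taken:
                k += 1
            cid = f"{cid}_atlas{k}"
        taken.add(cid)
        out.append(cid)
    return out


def merge_landmarks(
    landmarks: Landmarks,
    new_data: CountMatrix,
    features: FeatureSet,
    pseudocount: float = 0.1,
    atlas_node_size: int = 20,
) -> MergedMatrix:
    """Stack atlas nodes and new cells on the feature set, log-transform.

    Both sides must be CPM-normalized on a shared gene universe; the
    shifted log10 is applied uniformly after merging so landmarks and
    new cells are on the same scale.
    """
    if not new_data.normalized:
        raise DataValidationError("new dataset must be CPM-normalized")
    universe = set(new_data.gene_ids)
    missing = [g for g in features.genes if g not in universe]
    if missing:
        raise DataValidationError(f"features missing from new data: {missing[:10]}")
    if isinstance(landmarks, AtlasAverages):
        lm = landmarks.subset_genes(features.genes)
        atlas_values = lm.means.T
        atlas_ids = [str(t) for t in lm.cell_types]
        atlas_labels = list(lm.cell_types)
        atlas_sizes = np.full(len(atlas_ids), atlas_node_size, dtype=np.int64)
    elif isinstance(landmarks, AtlasSubsample):
        if not landmarks.matrix.normalized:
            raise DataValidationError("atlas subsample must be CPM-normalized")
        lm = landmarks.subset_genes(features.genes)
        atlas_values = lm.matrix.values
        atlas_ids = [str(c) for c in lm.matrix.cell_ids]
        atlas_labels = [lm.annotation.labels[c] for c in lm.matrix.cell_ids]
        atlas_sizes = np.ones(len(atlas_ids), dtype=np.int64)
    else:
        raise TypeError(f"unsupported landmark type {type(landmarks).__name__}")

    new_values = new_data.subset_genes(features.genes).values
    values = log_shift(
        np.concatenate([atlas_values, new_values], axis=1), pseudocount
    )
    atlas_ids = _dedupe_ids(atlas_ids, new_data.cell_ids)
    column_ids = pd.Index(atlas_ids + [str(c) for c in new_data.cell_ids])
    n_atlas, n_new = len(atlas_ids), new_data.n_cells
    return MergedMatrix(
        feature_ids=pd.Index(features.genes, dtype=object),
        column_ids=column_ids,
        values=values,
        is_atlas=np.array([True] * n_atlas + [False] * n_new),
        labels=np.array(atlas_labels + [None] * n_new, dtype=object),
        sizes=np.concatenate([atlas_sizes, np.ones(n_new, dtype=np.int64)]),
    )


def standardize_and_pca(m: MergedMatrix, p: GraphParams) -> np.ndarray:
    """Joint z-scoring, clipping at +-10, and PCA; returns columns x n_pcs.

    Zero-variance features are dropped before standardization. The sign
    of each component is fixed by making the largest-magnitude loading
    positive, so coordinates are reproducible across SVD backends.
    """
    if m.n_columns < 2:
        raise DataValidationError("PCA needs at least two columns")
    x = m.values
    std = x.std(axis=1)
    usable = std > 0
    if not usable.any():
        raise DataValidationError("all features have zero variance")
    z = (x[usable] - x[usable].mean(axis=1, keepdims=True)) / std[usable, None]
    z = np.clip(z, -10.0, 10.0)
    max_rank = min(int(usable.sum()), m.n_columns - 1)
    n_pcs = p.n_pcs
    if n_pcs > max_rank:
        warnings.warn(
            f"n_pcs={n_pcs} exceeds usable rank {max_rank}; clamping", stacklevel=2
        )
        n_pcs = max_rank
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=p.seed)
    coords = pca.fit_transform(z.T)
    # deterministic sign: largest-|.| loading of each component positive
    flip = np.empty(n_pcs)
    for i, load in enumerate(pca.components_):
        flip[i] = np.sign(load[np.argmax(np.abs(load))]) or 1.0
    return coords * flip[np.newaxis, :]


def _pairwise_distances(coords: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        from scipy.spatial.distance import squareform, pdist

        return squareform(pdist(coords))
    corr = np.corrcoef(coords)
    corr = np.nan_to_num(corr, nan=0.0)
    return 1.0 - corr


def build_graph(coords: np.ndarray, m: MergedMatrix, p: GraphParams) -> SimilarityGraph:
    """k-nearest-neighbor graph of new cells over all columns.

    Each NEW cell contributes edges to its ``k_neighbors`` nearest
    columns (new cells and atlas nodes alike); the edge set is the
    union over new cells, so atlas-atlas edges never arise. Ties are
    broken by column index. In correlation mode the edge weight is
    (1 + Pearson r of the coordinate vectors) / 2, pruned below
    ``weight_threshold``; in euclidean mode every kept edge has
    weight 1.
    """
    n = m.n_columns
    if coords.shape[0] != n:
        raise DataValidationError("coordinate rows do not align with columns")
    k = p.k_neighbors
    if k >= n:
        warnings.warn(f"k_neighbors={k} >= {n} columns; clamping", stacklevel=2)
        k = n - 1
    dist = _pairwise_distances(coords, p.metric)
    new_nodes = np.flatnonzero(~m.is_atlas)
    edge_set: dict = {}
    order_key = np.arange(n)
    for i in new_nodes:
        d = dist[i].copy()
        d[i] = np.inf
        # stable top-k: distance first, column index breaks ties
        nearest = np.lexsort((order_key, d))[:k]
        for j in nearest:
            if p.metric == "correlation":
                w = (1.0 - dist[i, j] + 1.0) / 2.0  # (1 + r) / 2
                if w < p.weight_threshold or w <= 0:
                    continue
                w = min(w, 1.0)
            else:
                w = 1.0
            edge = (min(i, int(j)), max(i, int(j)))
            edge_set.setdefault(edge, w)
    if edge_set:
        edges = np.array(sorted(edge_set), dtype=np.int64)
        weights = np.array([edge_set[tuple(e)] for e in edges])
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        weights = np.empty(0)
    g = SimilarityGraph(m.column_ids, m.is_atlas, m.labels, m.sizes, edges, weights)
    isolated = g.isolated_new_nodes()
    if len(isolated):
        warnings.warn(
            f"{len(isolated)} new cell(s) isolated after pruning, e.g. "
            f"{list(g.node_ids[isolated][:5])}",
            stacklevel=2,
        )
    return g
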