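"""Merging, PCA and similarity-graph construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlasguide import (
    AtlasAverages,
    FeatureSet,
    GraphParams,
    build_graph,
    merge_landmarks,
    normalize_cpm,
    standardize_and_pca,
    subsample_atlas,
)
from atlasguide.graph import MergedMatrix, SimilarityGraph, _pairwise_distances

from conftest import make_counts


def toy_merged(coords_like, is_atlas=None, sizes=None, labels=None):
    """MergedMatrix whose values don't matter; only column metadata does."""
    n = len(coords_like)
    is_atlas = np.array(is_atlas if is_atlas is not None else [False] * n)
    labels = np.array(
        labels if labels is not None
        else [f"T{i}" if a else None for i, a in enumerate(is_atlas)],
        dtype=object,
    )
    sizes = np.array(sizes if sizes is not None else [1] * n)
    return MergedMatrix(
        feature_ids=pd.Index(["f0", "f1"]),
        column_ids=pd.Index([f"n{i}" for i in range(n)]),
        values=np.zeros((2, n)),
        is_atlas=is_atlas,
        labels=labels,
        sizes=sizes,
    )


@pytest.fixture
def avg_landmarks(rng):
    means = rng.uniform(1, 100, size=(5, 40))
    return AtlasAverages([f"T{i}" for i in range(5)],
                         pd.Index([f"G{i}" for i in range(40)]),
                         means, np.full(5, 7))


class TestMergeLandmarks:
    def test_average_mode_bookkeeping(self, avg_landmarks, rng):
        new = normalize_cpm(make_counts(
            rng.poisson(20, (40, 100)) + 1.0,
            gene_ids=[f"G{i}" for i in range(40)],
            cell_ids=[f"cell{i}" for i in range(100)],
        ))
        features = FeatureSet([f"G{i}" for i in range(30)])
        merged = merge_landmarks(avg_landmarks, new, features)
        assert merged.values.shape == (30, 105)
        assert merged.is_atlas.sum() == 5
        assert list(merged.sizes[:5]) == [20] * 5
        assert list(merged.sizes[5:]) == [1] * 100

    def test_subsample_mode_column_count(self, small_atlas, rng):
        atlas, ann = small_atlas
        sub = subsample_atlas(atlas, ann, n_per_type=4, seed=0)
        new = normalize_cpm(make_counts(
            rng.poisson(20, (30, 50)) + 1.0,
            gene_ids=list(atlas.gene_ids),
            cell_ids=[f"newcell{i}" for i in range(50)],
        ))
        features = FeatureSet(list(atlas.gene_ids[:10]))
        merged = merge_landmarks(sub, new, features)
        assert merged.n_columns == 12 + 50
        assert merged.is_atlas.sum() == 12
        assert all(s == 1 for s in merged.sizes)

    def test_id_collision_suffixed_deterministically(self, avg_landmarks, rng):
        new = normalize_cpm(make_counts(
            rng.poisson(20, (40, 3)) + 1.0,
            gene_ids=[f"G{i}" for i in range(40)],
            cell_ids=["T0", "T1", "x"],  # collide with atlas type names
        ))
        features = FeatureSet([f"G{i}" for i in range(5)])
        m1 = merge_landmarks(avg_landmarks, new, features)
        m2 = merge_landmarks(avg_landmarks, new, features)
        assert list(m1.column_ids) == list(m2.column_ids)
        assert not m1.column_ids.has_duplicates
        assert "T0_atlas1" in m1.column_ids

    def test_missing_feature_is_named(self, avg_landmarks, rng):
        new = normalize_cpm(make_counts(
            rng.poisson(20, (40, 3)) + 1.0,
            gene_ids=[f"G{i}" for i in range(40)],
        ))
        features = FeatureSet(["G0", "NOT_A_GENE"])
        with pytest.raises(Exception, match="NOT_A_GENE"):
            merge_landmarks(avg_landmarks, new, features)


class TestStandardizeAndPca:
    def _merged_from_values(self, values):
        n_feat, n_col = values.shape
        return MergedMatrix(
            feature_ids=pd.Index([f"f{i}" for i in range(n_feat)]),
            column_ids=pd.Index([f"c{i}" for i in range(n_col)]),
            values=values,
            is_atlas=np.zeros(n_col, dtype=bool),
            labels=np.array([None] * n_col, dtype=object),
            sizes=np.ones(n_col, dtype=int),
        )

    def test_identical_columns_identical_coordinates(self, rng):
        col = rng.normal(size=12)
        values = np.column_stack([col, col, rng.normal(size=12)])
        coords = standardize_and_pca(self._merged_from_values(values),
                                     GraphParams(n_pcs=2))
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-10)

    def test_full_rank_preserves_pairwise_distances(self, rng):
        values = rng.normal(10, 3, size=(8, 6))
        m = self._merged_from_values(values)
        with pytest.warns(UserWarning, match="clamping"):
            coords = standardize_and_pca(m, GraphParams(n_pcs=8))
        z = (values - values.mean(axis=1, keepdims=True)) / \
            values.std(axis=1, keepdims=True)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(coords), pdist(np.clip(z, -10, 10).T),
                                   atol=1e-8)

    def test_duplicated_dataset_duplicates_coordinates(self, rng):
        values = rng.normal(5, 2, size=(10, 7))
        doubled = np.concatenate([values, values], axis=1)
        coords = standardize_and_pca(self._merged_from_values(doubled),
                                     GraphParams(n_pcs=3))
        np.testing.assert_allclose(coords[:7], coords[7:], atol=1e-8)

    def test_deterministic_across_calls(self, rng):
        values = rng.normal(size=(20, 15))
        m = self._merged_from_values(values)
        c1 = standardize_and_pca(m, GraphParams(n_pcs=5, seed=3))
        c2 = standardize_and_pca(m, GraphParams(n_pcs=5, seed=3))
        np.testing.assert_array_equal(c1, c2)


class TestBuildGraph:
    def test_new_cell_between_two_atlas_nodes(self):
        m = toy_merged(range(3), is_atlas=[True, True, False],
                       sizes=[20, 20, 1])
        coords = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        g = build_graph(coords, m, GraphParams(n_pcs=2, k_neighbors=2,
                                               metric="euclidean"))
        assert len(g.edges) == 2
        for u, v in g.edges:
            assert m.is_atlas[u] != m.is_atlas[v]

    def test_atlas_only_graph_has_no_edges(self):
        m = toy_merged(range(4), is_atlas=[True] * 4, sizes=[20] * 4)
        coords = np.random.default_rng(0).normal(size=(4, 2))
        g = build_graph(coords, m, GraphParams(n_pcs=2, k_neighbors=2,
                                               metric="euclidean"))
        assert len(g.edges) == 0

    def test_knn_matches_brute_force_oracle(self, rng):
        n, k = 30, 5
        coords = rng.normal(size=(n, 4))
        m = toy_merged(range(n))
        g = build_graph(coords, m, GraphParams(n_pcs=4, k_neighbors=k,
                                               metric="euclidean"))
        got = {tuple(e) for e in g.edges.tolist()}
        expect = set()
        for i in range(n):
            d = np.linalg.norm(coords - coords[i], axis=1)
            d[i] = np.inf
            for j in np.argsort(d, kind="stable")[:k]:
                expect.add((min(i, int(j)), max(i, int(j))))
        assert got == expect

    def test_correlation_weights_in_range_and_thresholded(self, rng):
        coords = rng.normal(size=(25, 6))
        m = toy_merged(range(25))
        g = build_graph(coords, m, GraphParams(n_pcs=6, k_neighbors=6,
                                               metric="correlation",
                                               weight_threshold=0.6))
        assert ((g.weights >= 0.6) & (g.weights <= 1.0)).all()

    def test_permutation_equivariance_in_new_cells(self, rng):
        n = 20
        coords = rng.normal(size=(n, 3))
        m = toy_merged(range(n))
        g1 = build_graph(coords, m, GraphParams(n_pcs=3, k_neighbors=4,
                                                metric="euclidean"))
        perm = rng.permutation(n)
        m2 = MergedMatrix(
            feature_ids=m.feature_ids,
            column_ids=m.column_ids[perm],
            values=m.values[:, perm],
            is_atlas=m.is_atlas[perm],
            labels=m.labels[perm],
            sizes=m.sizes[perm],
        )
        g2 = build_graph(coords[perm], m2, GraphParams(n_pcs=3, k_neighbors=4,
                                                       metric="euclidean"))
        e1 = {frozenset((g1.node_ids[u], g1.node_ids[v])) for u, v in g1.edges}
        e2 = {frozenset((g2.node_ids[u], g2.node_ids[v])) for u, v in g2.edges}
        assert e1 == e2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_never_contains_atlas_atlas_edges(self, seed):
        rng = np.random.default_rng(seed)
        n_atlas = int(rng.integers(1, 5))
        n_new = int(rng.integers(1, 15))
        n = n_atlas + n_new
        coords = rng.normal(size=(n, 3))
        m = toy_merged(range(n), is_atlas=[True] * n_atlas + [False] * n_new,
                       sizes=[20] * n_atlas + [1] * n_new)
        g = build_graph(coords, m, GraphParams(
            n_pcs=3, k_neighbors=int(rng.integers(1, 8)), metric="euclidean"))
        assert not (g.is_atlas[g.edges[:, 0]] & g.is_atlas[g.edges[:, 1]]).any()


def test_graph_tsv_round_trip(tmp_path, rng):
    from atlasguide import random_similarity_graph

    g = random_similarity_graph(seed=3, n_new=15, n_labels=2)
    g.write_tsv(tmp_path / "e.tsv", tmp_path / "n.tsv")
    back = SimilarityGraph.read_tsv(tmp_path / "e.tsv", tmp_path / "n.tsv")
    assert list(back.node_ids) == list(g.node_ids)
    np.testing.assert_array_equal(back.edges, g.edges)
    np.testing.assert_allclose(back.weights, g.weights)
    np.testing.assert_array_equal(back.is_atlas, g.is_atlas)
    assert list(back.labels) == list(g.labels)


def test_correlation_distance_matches_numpy(rng):
    coords = rng.normal(size=(10, 5))
    d = _pairwise_distances(coords, "correlation")
    expect = 1 - np.corrcoef(coords)
    np.testing.assert_allclose(d, expect, atol=1e-12)
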