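"""Atlas-constrained clustering: objective, guarantees, optimality."""

import itertools

import numpy as np
import pandas as pd
import pytest

from atlasguide import (
    ClusteringParams,
    ClusterWithAnnotations,
    DataValidationError,
    Membership,
    assign_labels,
    cluster_with_annotations,
    cpm_objective,
    random_similarity_graph,
)
from atlasguide.cluster import _optimize_once
from atlasguide.exact import exhaustive_best_partition
from atlasguide.graph import SimilarityGraph


def graph_from(edges_w, is_atlas, labels, sizes=None):
    n = len(is_atlas)
    sizes = sizes or [1] * n
    edges = np.array([(u, v) for u, v, _ in edges_w], dtype=np.int64).reshape(-1, 2)
    weights = np.array([w for *_, w in edges_w], dtype=float)
    return SimilarityGraph(
        pd.Index([f"n{i}" for i in range(n)]),
        np.array(is_atlas), np.array(labels, dtype=object),
        np.array(sizes, dtype=np.int64), edges, weights,
    )


class TestCpmObjective:
    def test_singletons_with_unit_sizes_score_zero(self):
        g = random_similarity_graph(seed=0, n_new=10, n_labels=2,
                                    atlas_mode="subsample", cells_per_label=1)
        np.testing.assert_allclose(
            cpm_objective(g, np.arange(g.n_nodes), gamma=0.7), 0.0
        )

    def test_unweighted_triangle_single_community(self):
        g = graph_from([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)],
                       [False] * 3, [None] * 3)
        assert cpm_objective(g, np.zeros(3), gamma=0.5) == pytest.approx(1.5)

    def test_matches_edge_by_edge_summation_oracle(self, rng):
        g = random_similarity_graph(seed=4, n_new=8, n_labels=2,
                                    edge_prob=0.5, atlas_edge_prob=0.5)
        part = rng.integers(0, 4, size=g.n_nodes)
        # force atlas nodes into their own blocks for a valid-ish partition
        gamma = 0.123
        expect = 0.0
        for (u, v), w in zip(g.edges, g.weights):
            if part[u] == part[v]:
                expect += w
        for c in set(part.tolist()):
            n_c = g.sizes[part == c].sum()
            expect -= gamma * n_c * (n_c - 1) / 2
        assert cpm_objective(g, part, gamma) == pytest.approx(expect)

    def test_agrees_with_leidenalg_quality(self):
        leidenalg = pytest.importorskip("leidenalg")
        g = random_similarity_graph(seed=5, n_new=30, n_labels=3)
        m = cluster_with_annotations(g, ClusteringParams(resolution=0.05, seed=1))
        part = leidenalg.CPMVertexPartition(
            g.to_igraph(),
            initial_membership=[int(c) for c in m.community],
            weights="weight",
            node_sizes=[int(s) for s in g.sizes],
            resolution_parameter=0.05,
        )
        # leidenalg counts each undirected edge twice in its quality
        assert part.quality() == pytest.approx(
            2.0 * cpm_objective(g, m.community, 0.05)
        )


class TestClusterWithAnnotations:
    def test_two_cliques_adopt_their_atlas_label(self):
        """Each 5-clique touches one atlas node; brute force agrees."""
        edges = []
        # atlas nodes 0 (A) and 1 (B); cliques 2-6 and 7-11
        for a, b in itertools.combinations(range(2, 7), 2):
            edges.append((a, b, 1.0))
        for a, b in itertools.combinations(range(7, 12), 2):
            edges.append((a, b, 1.0))
        edges.append((0, 2, 1.0))
        edges.append((1, 7, 1.0))
        g = graph_from(edges, [True, True] + [False] * 10,
                       ["A", "B"] + [None] * 10)
        gamma = 0.001
        m = cluster_with_annotations(g, ClusteringParams(resolution=gamma, seed=0))
        labels = assign_labels(m)
        for i in range(2, 7):
            assert labels.loc[f"n{i}", "assigned_label"] == "A"
        for i in range(7, 12):
            assert labels.loc[f"n{i}", "assigned_label"] == "B"
        assert not labels["is_novel"].any()
        best_obj, _ = exhaustive_best_partition(g, gamma)
        assert cpm_objective(g, m.community, gamma) == pytest.approx(best_obj)

    def test_disconnected_new_cells_never_get_atlas_label(self):
        edges = [(0, 1, 0.9), (2, 3, 0.9), (3, 4, 0.9), (2, 4, 0.9)]
        g = graph_from(edges, [True, False, False, False, False],
                       ["A", None, None, None, None])
        m = cluster_with_annotations(g, ClusteringParams(resolution=0.01, seed=0))
        labels = assign_labels(m)
        assert labels.loc["n1", "assigned_label"] == "A"
        for i in (2, 3, 4):
            assert labels.loc[f"n{i}", "assigned_label"].startswith("novel_")

    def test_atlas_only_graph_returns_seed_communities(self):
        g = graph_from([], [True, True, True], ["A", "A", "B"])
        gamma = 0.2
        m = cluster_with_annotations(g, ClusteringParams(resolution=gamma))
        assert m.n_communities == 2
        assert sorted(filter(None, m.community_labels)) == ["A", "B"]
        assert cpm_objective(g, m.community, gamma) == pytest.approx(
            -gamma * (2 * 1) / 2 * 1 - 0.0
        )

    def test_empty_graph_errors(self):
        g = graph_from([], [], [])
        with pytest.raises(DataValidationError, match="empty"):
            cluster_with_annotations(g)

    @pytest.mark.parametrize("atlas_mode", ["averages", "subsample"])
    def test_atlas_fidelity_on_random_graphs(self, atlas_mode):
        """No split, no merge, full partition — structural guarantees."""
        for seed in range(25):
            g = random_similarity_graph(seed=seed, n_new=30, n_labels=3,
                                        atlas_mode=atlas_mode)
            m = cluster_with_annotations(
                g, ClusteringParams(resolution=0.01, seed=seed)
            )
            m.validate_against(g)  # raises on any violation

    def test_determinism(self):
        g = random_similarity_graph(seed=11, n_new=40, n_labels=4)
        p = ClusteringParams(resolution=0.005, seed=99)
        m1 = cluster_with_annotations(g, p)
        m2 = cluster_with_annotations(g, p)
        np.testing.assert_array_equal(m1.community, m2.community)
        assert m1.community_labels == m2.community_labels

    def test_monotone_objective_improvement(self):
        for seed in range(10):
            g = random_similarity_graph(seed=seed, n_new=25, n_labels=3)
            trace: list = []
            cluster_with_annotations(
                g, ClusteringParams(resolution=0.02, seed=seed), trace=trace
            )
            for run in trace:
                diffs = np.diff(run)
                assert (diffs >= -1e-9).all()

    def test_terminal_node_optimality(self):
        """Exhaustive single-move audit finds no improving move."""
        for seed in range(5):
            g = random_similarity_graph(seed=seed, n_new=30, n_labels=3)
            gamma = 0.01
            m = cluster_with_annotations(g, ClusteringParams(resolution=gamma,
                                                             seed=seed))
            base = cpm_objective(g, m.community, gamma)
            new_nodes = np.flatnonzero(~g.is_atlas)
            targets = set(m.community.tolist())
            fresh = max(targets) + 1
            for v in new_nodes:
                for target in sorted(targets | {fresh}):
                    if target == m.community[v]:
                        continue
                    trial = m.community.copy()
                    trial[v] = target
                    assert cpm_objective(g, trial, gamma) <= base + 1e-9

    def test_matches_exhaustive_optimum_on_tiny_graphs(self):
        hits = 0
        for trial in range(30):
            rng = np.random.default_rng(trial)
            gamma = float(rng.uniform(0.005, 0.1))
            g = random_similarity_graph(
                seed=trial, n_new=6, n_labels=int(rng.integers(2, 4)),
                atlas_mode="subsample", cells_per_label=2,
                edge_prob=0.4, atlas_edge_prob=0.4,
            )
            best_obj, _ = exhaustive_best_partition(g, gamma)
            m = cluster_with_annotations(g, ClusteringParams(resolution=gamma,
                                                             seed=trial))
            if cpm_objective(g, m.community, gamma) >= best_obj - 1e-9:
                hits += 1
        assert hits >= 28

    def test_resolution_monotonicity_of_novel_cluster_count(self):
        g = random_similarity_graph(seed=21, n_new=50, n_labels=3,
                                    edge_prob=0.1, atlas_edge_prob=0.15)
        counts = []
        for gamma in (0.001, 0.01, 0.05, 0.2, 0.8):
            m = cluster_with_annotations(g, ClusteringParams(resolution=gamma,
                                                             seed=0))
            novel = sum(1 for lab in m.community_labels if lab is None)
            counts.append(novel)
        assert counts == sorted(counts)


class TestAssignLabels:
    def _membership(self, community, labels, is_atlas=None):
        n = len(community)
        is_atlas = np.array(is_atlas if is_atlas is not None else [False] * n)
        return Membership(pd.Index([f"n{i}" for i in range(n)]),
                          is_atlas, np.array(community), labels)

    def test_all_labeled_communities_no_novel(self):
        m = self._membership([0, 0, 1, 1], ["A", "B"],
                             is_atlas=[True, False, True, False])
        out = assign_labels(m)
        assert not out["is_novel"].any()
        assert list(out["assigned_label"]) == ["A", "B"]

    def test_novel_numbering_by_decreasing_size(self):
        community = [0] * 3 + [1] * 10
        m = self._membership(community, [None, None])
        out = assign_labels(m)
        big = out[out["community_id"] == 1]
        small = out[out["community_id"] == 0]
        assert set(big["assigned_label"]) == {"novel_1"}
        assert set(small["assigned_label"]) == {"novel_2"}

    def test_counts_match_group_by_tally(self):
        rng = np.random.default_rng(8)
        g = random_similarity_graph(seed=8, n_new=40, n_labels=3)
        m = cluster_with_annotations(g, ClusteringParams(resolution=0.01))
        out = assign_labels(m)
        tally = out.groupby("assigned_label").size()
        for label, count in tally.items():
            assert (out["assigned_label"] == label).sum() == count
        assert len(out) == (~g.is_atlas).sum()

    def test_min_size_flags_unassigned(self):
        community = [0] * 2 + [1] * 10
        m = self._membership(community, [None, None])
        out = assign_labels(m, min_novel_cluster_size=5)
        assert set(out[out["community_id"] == 0]["assigned_label"]) == {"unassigned"}


def test_cluster_with_annotations_class_wrapper():
    g = random_similarity_graph(seed=2, n_new=20, n_labels=2)
    model = ClusterWithAnnotations(resolution=0.01, seed=0)
    m = model.fit(g)
    assert model.membership_ is m
    assert len(model.assignment_) == 20
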