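"""Atlas-constrained community detection (``ClusterWithAnnotations``).

The similarity graph is partitioned by a Leiden-style local-move
procedure maximizing a size-weighted constant Potts model (CPM)
objective,

    Q = sum over communities c of [ W_c - gamma * N_c (N_c - 1) / 2 ]

where ``W_c`` is the total intra-community edge weight and ``N_c`` the
sum of node sizes in ``c``. The twist that makes the clustering
atlas-aware: all atlas nodes of one cell type start in one seed
community and NEVER move, and two labeled communities are never merged.
Consequently atlas cell types can neither split nor merge — they are
fully determined by the atlas — while new cells are free to join a
type's community or to assemble into novel clusters.

Within each sweep new nodes are visited in a seeded random permutation
and greedily moved to the neighboring community (or a fresh singleton)
with the largest positive objective gain. Once single-node moves are
exhausted, coarser positive-gain moves are tried (the aggregation
analog of Leiden): whole unlabeled communities merge into adjacent
ones (labeled-labeled merges are excluded), the set of new members of
any community can relocate as a unit, and adjacent same-community
pairs can move jointly. Several seeded restarts are run and the best
partition kept. The procedure terminates at a node-optimal partition:
no single new-node move can increase the objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataValidationError
from .graph import SimilarityGraph

_EPS = 1e-12


@dataclass
class ClusteringParams:
    """Resolution and bookkeeping knobs of the constrained clustering.

    resolution
        CPM resolution gamma; with node sizes in play, values below
        0.01 avoid splitting coherent populations into subclusters.
    seed
        Seed of the sweep permutation generator.
    max_sweeps
        Hard cap on local-move sweeps.
    n_restarts
        Independent seeded optimization runs; the partition with the
        best objective wins. Greedy local search can stall in local
        optima on adversarial graphs; a few restarts with different
        sweep permutations escape most of them.
    min_novel_cluster_size
        Novel communities smaller than this are flagged "unassigned"
        during label assignment (0 disables the filter).
    """

    resolution: float = 0.001
    seed: int = 0
    max_sweeps: int = 100
    n_restarts: int = 5
    min_novel_cluster_size: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.max_sweeps < 1 or self.n_restarts < 1:
            raise ValueError("max_sweeps and n_restarts must be >= 1")
        if self.min_novel_cluster_size < 0:
            raise ValueError("min_novel_cluster_size must be >= 0")


@dataclass
class Membership:
    """A partition of graph nodes with per-community atlas labels."""

    node_ids: pd.Index
    is_atlas: np.ndarray
    community: np.ndarray  # community id per node, compacted 0..C-1
    community_labels: list  # per community: atlas label or None

    def __post_init__(self) -> None:
        self.community = np.asarray(self.community, dtype=np.int64)
        n_comm = len(self.community_labels)
        if len(self.community) and (
            self.community.min() < 0 or self.community.max() >= n_comm
        ):
            raise DataValidationError("community ids out of range")

    @property
    def n_communities(self) -> int:
        return len(self.community_labels)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.community == c)

    def validate_against(self, g: SimilarityGraph) -> None:
        """Check the no-split / no-merge guarantees structurally."""
        if len(self.community) != g.n_nodes:
            raise DataValidationError("membership does not cover the graph")
        label_to_comm: dict = {}
        for v in np.flatnonzero(g.is_atlas):
            c = int(self.community[v])
            label = g.labels[v]
            if self.community_labels[c] != label:
                raise DataValidationError(
                    f"atlas node {g.node_ids[v]} sits in a community "
                    f"labeled {self.community_labels[c]!r}, not {label!r}"
                )
            if label_to_comm.setdefault(label, c) != c:
                raise DataValidationError(f"atlas type {label!r} is split")
        comm_to_label: dict = {}
        for label, c in label_to_comm.items():
            if comm_to_label.setdefault(c, label) != label:
                raise DataValidationError("two atlas labels share a community")


def cpm_objective(g: SimilarityGraph, community: np.ndarray, gamma: float) -> float:
    """Size-weighted constant Potts model quality of a partition."""
    community = np.asarray(community)
    same = community[g.edges[:, 0]] == community[g.edges[:, 1]]
    intra = float(g.weights[same].sum()) if len(g.weights) else 0.0
    penalty = 0.0
    for c in np.unique(community):
        n_c = float(g.sizes[community == c].sum())
        penalty += n_c * (n_c - 1.0) / 2.0
    return intra - gamma * penalty


class _State:
    """Mutable partition state during optimization."""

    def __init__(self, g: SimilarityGraph, gamma: float):
        self.g = g
        self.gamma = gamma
        self.adj = g.adjacency()
        self.sizes = g.sizes.astype(np.float64)
        self.comm = np.empty(g.n_nodes, dtype=np.int64)
        self.comm_size: list[float] = []
        self.comm_label: list = []
        self.comm_members: list[set] = []
        # seed communities: one per atlas label, then singleton new cells
        label_comm: dict = {}
        for v in range(g.n_nodes):
            if g.is_atlas[v]:
                label = g.labels[v]
                if label is None:
                    raise DataValidationError("atlas node missing a label")
                if label not in label_comm:
                    label_comm[label] = self._new_community(label)
                self._place(v, label_comm[label])
            else:
                self._place(v, self._new_community(None))

    def _new_community(self, label) -> int:
        self.comm_size.append(0.0)
        self.comm_label.append(label)
        self.comm_members.append(set())
        return len(self.comm_size) - 1

    def _place(self, v: int, c: int) -> None:
        self.comm[v] = c
        self.comm_size[c] += self.sizes[v]
        self.comm_members[c].add(v)

    def _remove(self, v: int) -> int:
        c = int(self.comm[v])
        self.comm_size[c] -= self.sizes[v]
        self.comm_members[c].discard(v)
        return c

    def neighbor_comm_weights(self, v: int) -> dict:
        w: dict = {}
        for j, wt in self.adj[v]:
            cj = int(self.comm[j])
            w[cj] = w.get(cj, 0.0) + wt
        return w

    def local_sweep(self, order: np.ndarray) -> int:
        """One pass of greedy single-node moves; returns #moves."""
        gamma, sizes = self.gamma, self.sizes
        moves = 0
        for v in order:
            v = int(v)
            c = int(self.comm[v])
            w_to = self.neighbor_comm_weights(v)
            # cost of leaving the current community
            w_stay = w_to.get(c, 0.0)
            leave_gain = -w_stay + gamma * sizes[v] * (self.comm_size[c] - sizes[v])
            best_c, best_gain = c, 0.0
            for d, w in w_to.items():
                if d == c:
                    continue
                gain = leave_gain + w - gamma * sizes[v] * self.comm_size[d]
                if gain > best_gain + _EPS:
                    best_c, best_gain = d, gain
            # a fresh singleton (w = 0, empty community)
            if leave_gain > best_gain + _EPS and len(self.comm_members[c]) > 1:
                best_c, best_gain = self._new_community(None), leave_gain
            if best_c != c:
                self._remove(v)
                self._place(v, best_c)
                moves += 1
        return moves

    def merge_sweep(self) -> int:
        """Merge unlabeled communities into adjacent ones when profitable."""
        gamma = self.gamma
        merges = 0
        for c in range(len(self.comm_label)):
            if self.comm_label[c] is not None or not self.comm_members[c]:
                continue
            # inter-community weights from c's members
            w_out: dict = {}
            for v in self.comm_members[c]:
                for j, wt in self.adj[v]:
                    d = int(self.comm[j])
                    if d != c:
                        w_out[d] = w_out.get(d, 0.0) + wt
            best_d, best_gain = -1, 0.0
            for d, w in sorted(w_out.items()):
                gain = w - gamma * self.comm_size[c] * self.comm_size[d]
                if gain > best_gain + _EPS:
                    best_d, best_gain = d, gain
            if best_d >= 0:
                for v in list(self.comm_members[c]):
                    self._remove(v)
                    self._place(v, best_d)
                merges += 1
        return merges

    def _subset_out_weights(self, members) -> dict:
        """Edge weight from a node set to each outside community."""
        inside = set(members)
        w: dict = {}
        for v in inside:
            for j, wt in self.adj[v]:
                if j in inside:
                    continue
                d = int(self.comm[j])
                w[d] = w.get(d, 0.0) + wt
        return w

    def _move_subset(self, members, d: int) -> None:
        for v in list(members):
            self._remove(v)
            self._place(v, d)

    def _best_subset_move(self, members, c: int, allow_fresh: bool) -> tuple:
        """(gain, target) of moving a same-community new-node set."""
        gamma = self.gamma
        sigma = float(sum(self.sizes[v] for v in members))
        w = self._subset_out_weights(members)
        leave_gain = -w.get(c, 0.0) + gamma * sigma * (self.comm_size[c] - sigma)
        best_d, best_gain = c, 0.0
        for d in sorted(k for k in w if k != c):
            gain = leave_gain + w[d] - gamma * sigma * self.comm_size[d]
            if gain > best_gain + _EPS:
                best_d, best_gain = d, gain
        if allow_fresh and leave_gain > best_gain + _EPS:
            best_d, best_gain = -1, leave_gain
        return best_gain, best_d

    def relocate_sweep(self) -> int:
        """Move the whole set of NEW members of a community elsewhere.

        Unlike a community merge this is legal even for labeled
        communities: the atlas nodes stay behind, only the attached new
        cells are relocated as a unit.
        """
        moves = 0
        for c in range(len(self.comm_label)):
            members = [v for v in self.comm_members[c] if not self.g.is_atlas[v]]
            if not members:
                continue
            partial = len(members) < len(self.comm_members[c])
            gain, d = self._best_subset_move(members, c, allow_fresh=partial)
            if d != c:
                if d == -1:
                    d = self._new_community(None)
                self._move_subset(members, d)
                moves += 1
        return moves

    def pair_sweep(self) -> int:
        """Joint moves of adjacent same-community pairs of new nodes."""
        moves = 0
        for (u, v), _ in zip(self.g.edges, self.g.weights):
            u, v = int(u), int(v)
            if self.g.is_atlas[u] or self.g.is_atlas[v]:
                continue
            c = int(self.comm[u])
            if int(self.comm[v]) != c:
                continue
            pair = (u, v)
            allow_fresh = len(self.comm_members[c]) > 2
            gain, d = self._best_subset_move(pair, c, allow_fresh)
            if d != c:
                if d == -1:
                    d = self._new_community(None)
                self._move_subset(pair, d)
                moves += 1
        return moves

    def to_membership(self) -> Membership:
        """Compact community ids to 0..C-1 in order of first appearance."""
        remap: dict = {}
        out = np.empty_like(self.comm)
        labels: list = []
        for v, c in enumerate(self.comm):
            c = int(c)
            if c not in remap:
                remap[c] = len(labels)
                labels.append(self.comm_label[c])
            out[v] = remap[c]
        return Membership(self.g.node_ids, self.g.is_atlas, out, labels)


def _optimize_once(g: SimilarityGraph, params: ClusteringParams,
                   seed: int, trace: list | None = None) -> _State:
    """One full optimization run from the seed partition.

    ``trace``, when given, collects the objective after every sweep so
    callers can audit monotone improvement.
    """
    state = _State(g, params.resolution)

    def record() -> None:
        if trace is not None:
            trace.append(cpm_objective(g, state.comm, params.resolution))

    new_nodes = np.flatnonzero(~g.is_atlas)
    record()
    if len(new_nodes) == 0:
        return state
    rng = np.random.default_rng(seed)
    for _ in range(params.max_sweeps):
        moved = state.local_sweep(rng.permutation(new_nodes))
        record()
        if moved > 0:
            continue
        # coarser escape moves, tried only at single-node optimality
        if state.merge_sweep() > 0:
            record()
            continue
        if state.relocate_sweep() > 0:
            record()
            continue
        if state.pair_sweep() > 0:
            record()
            continue
        break
    # final polish guarantees node-optimality after any subset moves
    while state.local_sweep(rng.permutation(new_nodes)) > 0:
        record()
    return state


def cluster_with_annotations(
    g: SimilarityGraph, params: ClusteringParams | None = None,
    trace: list | None = None,
) -> Membership:
    """Partition the graph with atlas types fixed; see module docstring.

    Runs ``n_restarts`` seeded optimizations and keeps the partition
    with the best objective. The result satisfies the
    no-split/no-merge guarantees and is deterministic given
    (graph, params). ``trace``, when given, receives one
    objective-per-sweep list per restart.
    """
    if params is None:
        params = ClusteringParams()
    if g.n_nodes == 0:
        raise DataValidationError("cannot cluster an empty graph")
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(params.seed).spawn(params.n_restarts)
    ]
    best_state, best_obj = None, -np.inf
    for s in seeds:
        run_trace: list | None = [] if trace is not None else None
        state = _optimize_once(g, params, s, run_trace)
        if trace is not None:
            trace.append(run_trace)
        obj = cpm_objective(g, state.comm, params.resolution)
        if obj > best_obj + _EPS:
            best_state, best_obj = state, obj
    membership = best_state.to_membership()
    membership.validate_against(g)
    return membership


def assign_labels(
    m: Membership, min_novel_cluster_size: int = 0
) -> pd.DataFrame:
    """Per-new-cell assignment: an atlas label or ``novel_<j>``.

    Unlabeled communities are numbered ``novel_1, novel_2, ...`` by
    decreasing size (node count), ties broken by smallest member index.
    Novel communities below ``min_novel_cluster_size`` are flagged
    ``unassigned``. Returns a frame indexed by new-cell id with columns
    (assigned_label, community_id, is_novel).
    """
    novel = [
        c for c in range(m.n_communities) if m.community_labels[c] is None
    ]
    novel.sort(key=lambda c: (-len(m.members(c)), int(m.members(c).min())))
    novel_names: dict = {}
    for j, c in enumerate(novel, start=1):
        if len(m.members(c)) < min_novel_cluster_size:
            novel_names[c] = "unassigned"
        else:
            novel_names[c] = f"novel_{j}"
    rows = []
    for v in np.flatnonzero(~m.is_atlas):
        c = int(m.community[v])
        label = m.community_labels[c]
        rows.append(
            (m.node_ids[v], label if label is not None else novel_names[c],
             c, label is None)
        )
    df = pd.DataFrame(rows, columns=["cell_id", "assigned_label",
                                     "community_id", "is_novel"])
    return df.set_index("cell_id")


class ClusterWithAnnotations:
    """Object-style entry point for custom similarity graphs.

    Users who build their own graph (e.g. after external data
    harmonization) can cluster it with the same atlas-aware guarantees:

    >>> model = ClusterWithAnnotations(resolution=0.001, seed=0)
    >>> membership = model.fit(graph)
    >>> assignment = model.assignment_
    """

    def __init__(self, resolution: float = 0.001, seed: int = 0,
                 max_sweeps: int = 100, min_novel_cluster_size: int = 0):
        self.params = ClusteringParams(resolution=resolution, seed=seed,
                                       max_sweeps=max_sweeps,
                                       min_novel_cluster_size=min_novel_cluster_size)

    def fit(self, g: SimilarityGraph) -> Membership:
        self.membership_ = cluster_with_annotations(g, self.params)
        self.assignment_ = assign_labels(
            self.membership_, self.params.min_novel_cluster_size
        )
        return self.membership_
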