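"""Exact constrained-partition optimum by exhaustive enumeration.

For small graphs (roughly <= 14 nodes) every label-respecting partition
can be enumerated: each atlas label's nodes form one mandatory block,
two labeled blocks never share a community, and new nodes are placed
freely. This gives the exact maximum of the size-weighted CPM
objective, used to verify the heuristic clustering — it shares no code
with the sweep-based optimizer.
"""

from __future__ import annotations

import numpy as np

from .graph import SimilarityGraph


def exhaustive_best_partition(
    g: SimilarityGraph, gamma: float
) -> tuple[float, np.ndarray]:
    """Return (best objective, community id per node).

    Enumerates assignments by placing new nodes one at a time into any
    existing block or a fresh one, accumulating the objective
    incrementally. Exponential in the number of new nodes; intended for
    verification on tiny graphs only.
    """
    n = g.n_nodes
    if n > 16:
        raise ValueError("exhaustive enumeration is limited to tiny graphs")
    w = np.zeros((n, n))
    for (u, v), wt in zip(g.edges, g.weights):
        w[u, v] += wt
        w[v, u] += wt
    sizes = g.sizes.astype(float)

    # mandatory blocks: one per atlas label
    labels = [g.labels[v] for v in range(n) if g.is_atlas[v]]
    label_order = list(dict.fromkeys(labels))
    blocks: list[list[int]] = [
        [v for v in range(n) if g.is_atlas[v] and g.labels[v] == lab]
        for lab in label_order
    ]
    new_nodes = [v for v in range(n) if not g.is_atlas[v]]

    base_obj = 0.0
    block_sizes = []
    for members in blocks:
        s = sizes[members].sum()
        block_sizes.append(s)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                base_obj += w[u, v]
        base_obj -= gamma * s * (s - 1.0) / 2.0
    # size self-term of each new node, constant across assignments
    for v in new_nodes:
        base_obj -= gamma * sizes[v] * (sizes[v] - 1.0) / 2.0

    best = {"obj": -np.inf, "assign": None}
    assign = np.full(n, -1, dtype=np.int64)
    for b, members in enumerate(blocks):
        for v in members:
            assign[v] = b
    n_fixed = len(blocks)
    block_sizes = list(block_sizes) + [0.0] * len(new_nodes)
    members_of: list[list[int]] = [list(b) for b in blocks] + [
        [] for _ in new_nodes
    ]
    n_open = n_fixed  # blocks currently in use

    def place(idx: int, obj: float) -> None:
        nonlocal n_open
        if idx == len(new_nodes):
            if obj > best["obj"]:
                best["obj"] = obj
                best["assign"] = assign.copy()
            return
        v = new_nodes[idx]
        # join an existing block, or open block n_open as a fresh one
        for b in range(n_open + 1):
            members = members_of[b]
            gain = sum(w[v, u] for u in members)
            gain -= gamma * sizes[v] * block_sizes[b]
            opened = b == n_open
            if opened:
                n_open += 1
            members.append(v)
            block_sizes[b] += sizes[v]
            assign[v] = b
            place(idx + 1, obj + gain)
            members.pop()
            block_sizes[b] -= sizes[v]
            assign[v] = -1
            if opened:
                n_open -= 1

    place(0, base_obj)
    return float(best["obj"]), best["assign"]
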