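"""Cluster a self-built similarity graph with atlas constraints.

The clustering stage is exposed on its own: any similarity graph —
e.g. one built after external batch correction or harmonization — can
be partitioned with the same guarantee that atlas cell types neither
split nor merge. Here the graph is assembled step by step from the
library's own building blocks instead of calling the one-shot
pipeline, which is exactly what a custom-harmonization user would do.
"""

import warnings

import atlasguide as ag
from atlasguide.cluster import cpm_objective

params = ag.default_simulation(seed=2)
atlas_counts, annotation, new_counts, truth = ag.simulate(params)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    atlas_counts, new_counts = ag.intersect_genes(atlas_counts, new_counts)
    atlas_cpm = ag.normalize_cpm(atlas_counts)
    new_cpm = ag.normalize_cpm(new_counts)
    landmarks = ag.compute_averages(atlas_cpm, annotation)

    features = ag.select_features(landmarks, new_cpm, ag.FeatureParams())
    merged = ag.merge_landmarks(landmarks, new_cpm, features)
    graph_params = ag.GraphParams(seed=2)
    coords = ag.standardize_and_pca(merged, graph_params)
    graph = ag.build_graph(coords, merged, graph_params)

print(f"graph: {graph.n_nodes} nodes "
      f"({int(graph.is_atlas.sum())} atlas), {len(graph.weights)} edges")

# any graph with the same node metadata could be substituted here
model = ag.ClusterWithAnnotations(resolution=0.001, seed=0)
membership = model.fit(graph)
membership.validate_against(graph)  # no-split / no-merge guarantee

print(f"communities: {membership.n_communities}")
for label, n in model.assignment_["assigned_label"].value_counts().items():
    print(f"  {label:>8}: {n} new cells")
print("CPM objective: "
      f"{cpm_objective(graph, membership.community, 0.001):.3f}")
# every atlas label owns exactly one community; groups of new cells
# without a matching atlas type end up in novel_<j> clusters.
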