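"""End-to-end annotation pipeline.

Ties the stages together: gene intersection, CPM normalization,
landmark compression (or loading precomputed landmarks), feature
selection, merging, PCA, graph construction, atlas-constrained
clustering, and label assignment. The library entry point is
:func:`annotate`; the CLI wraps it thinly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from . import core
from .cluster import ClusteringParams, Membership, assign_labels, cluster_with_annotations
from .core import CellAnnotation, CountMatrix, DataValidationError
from .features import FeatureParams, FeatureSet, select_features
from .graph import GraphParams, SimilarityGraph, build_graph, merge_landmarks, standardize_and_pca
from .landmarks import (
    AtlasAverages,
    AtlasSubsample,
    Landmarks,
    compute_averages,
    exclude_ambiguous_types,
    subsample_atlas,
)

logger = logging.getLogger("atlasguide")


@dataclass
class RunConfig:
    """Fully resolved parameters of one annotation run."""

    landmark_mode: str = "average"  # "average" | "subsample"
    n_per_type: int = 20
    min_total_counts: float | None = None
    features: FeatureParams = field(default_factory=FeatureParams)
    graph: GraphParams = field(default_factory=GraphParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.landmark_mode not in ("average", "subsample"):
            raise ValueError(f"unknown landmark mode {self.landmark_mode!r}")
        if self.n_per_type < 1:
            raise ValueError("n_per_type must be >= 1")
        # one seed steers every stochastic stage unless overridden
        self.graph = dataclasses.replace(self.graph, seed=self.seed)
        self.clustering = dataclasses.replace(self.clustering, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AnnotationResult:
    """Everything one annotation run produced."""

    assignment: pd.DataFrame  # per new cell: assigned_label, community_id, is_novel
    membership: Membership
    graph: SimilarityGraph
    features: FeatureSet
    landmarks: Landmarks
    normalized_new: CountMatrix
    config: RunConfig
    report: dict

    def novel_clusters(self) -> dict[str, list]:
        """Novel-cluster name -> member new-cell ids."""
        novel = self.assignment[self.assignment["is_novel"]]
        return {
            name: grp.index.tolist()
            for name, grp in novel.groupby("assigned_label", sort=True)
            if name != "unassigned"
        }

    def write(self, out_dir) -> None:
        """Write assignment TSV and JSON run report into ``out_dir``."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        tsv = os.path.join(out_dir, "assignment.tsv")
        with open(tsv, "w") as fh:
            fh.write(f"# config_hash: {self.config.config_hash()}\n")
            self.assignment.to_csv(fh, sep="\t")
        with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
            json.dump(self.report, fh, indent=1, default=str)
            fh.write("\n")


def _prepare_landmarks(
    atlas: CountMatrix, annotation: CellAnnotation, config: RunConfig
) -> Landmarks:
    annotation = exclude_ambiguous_types(annotation, annotation.ambiguous_labels)
    keep = atlas.cell_ids[atlas.cell_ids.isin(annotation.cell_ids)]
    if len(keep) == 0:
        raise DataValidationError("no annotated, unambiguous atlas cells remain")
    atlas = atlas.subset_cells(keep)
    if config.landmark_mode == "average":
        return compute_averages(atlas, annotation)
    return subsample_atlas(atlas, annotation, config.n_per_type, config.seed)


def annotate(
    new_data: CountMatrix,
    atlas: CountMatrix | None = None,
    annotation: CellAnnotation | None = None,
    landmarks: Landmarks | None = None,
    config: RunConfig | None = None,
) -> AnnotationResult:
    """Annotate new cells against an atlas (counts or landmarks).

    Either ``atlas`` + ``annotation`` (raw or CPM counts plus a
    cell->type mapping) or precomputed ``landmarks`` must be supplied.
    ``new_data`` holds raw counts. Returns an
    :class:`AnnotationResult`; every new cell ends up with an atlas
    label or a ``novel_<j>`` cluster.
    """
    if config is None:
        config = RunConfig()
    if new_data.n_cells == 0:
        raise DataValidationError("new dataset has no cells")
    if (landmarks is None) == (atlas is None):
        raise DataValidationError(
            "supply either an atlas (counts + annotation) or landmarks, not both"
        )
    timings: dict = {}
    t0 = time.perf_counter()

    def tick(stage: str) -> None:
        nonlocal t0
        timings[stage] = round(time.perf_counter() - t0, 4)
        logger.info("stage %-12s %.3fs", stage, timings[stage])
        t0 = time.perf_counter()

    try:
        if config.min_total_counts is not None and not new_data.normalized:
            new_data = core.filter_cells(new_data, config.min_total_counts)

        if atlas is not None:
            if annotation is None:
                raise DataValidationError("atlas counts need an annotation")
            atlas, new_data = core.intersect_genes(atlas, new_data)
            new_data = core.drop_zero_cells(new_data)
            if not atlas.normalized:
                atlas = core.normalize_cpm(atlas)
            if not new_data.normalized:
                new_data = core.normalize_cpm(new_data)
            landmarks = _prepare_landmarks(atlas, annotation, config)
        else:
            # precomputed landmarks: intersect on their gene universe
            lm_genes = landmarks.gene_ids
            shared = new_data.gene_ids[new_data.gene_ids.isin(lm_genes)]
            if len(shared) == 0:
                raise DataValidationError(
                    "empty gene intersection between landmarks and new data"
                )
            landmarks = landmarks.subset_genes(shared)
            new_data = new_data.subset_genes(shared)
            new_data = core.drop_zero_cells(new_data)
            if not new_data.normalized:
                new_data = core.normalize_cpm(new_data)
        tick("prepare")

        features = select_features(landmarks, new_data, config.features)
        tick("features")

        merged = merge_landmarks(
            landmarks, new_data, features,
            pseudocount=config.features.pseudocount,
            atlas_node_size=config.graph.atlas_node_size,
        )
        coords = standardize_and_pca(merged, config.graph)
        graph = build_graph(coords, merged, config.graph)
        tick("graph")

        membership = cluster_with_annotations(graph, config.clustering)
        assignment = assign_labels(
            membership, config.clustering.min_novel_cluster_size
        )
        tick("cluster")
    except DataValidationError:
        raise
    except Exception as exc:  # surface the failing stage
        stage = "prepare" if not timings else list(timings)[-1]
        raise RuntimeError(f"annotation failed after stage {stage!r}: {exc}") from exc

    counts = assignment["assigned_label"].value_counts().to_dict()
    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_new_cells": int(new_data.n_cells),
        "n_features": len(features),
        "n_graph_edges": int(len(graph.weights)),
        "n_communities": membership.n_communities,
        "cells_per_label": counts,
        "timings_s": timings,
    }
    return AnnotationResult(
        assignment=assignment,
        membership=membership,
        graph=graph,
        features=features,
        landmarks=landmarks,
        normalized_new=new_data,
        config=config,
        report=report,
    )
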