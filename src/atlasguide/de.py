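"""One-vs-rest differential expression for novel clusters.

The recipe: average CPM expression inside vs outside the cluster,
shortlist the genes with the highest (pseudocounted) fold changes, then
rank the shortlist by the two-sample Kolmogorov-Smirnov statistic
computed on per-cell CPM values. The KS statistic — the largest gap
between the two empirical CDFs — rewards genes expressed by many cells
inside the cluster and few outside, not just genes with a large mean
shift driven by a handful of cells. Ranking is by statistic; p-values
are deliberately not computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import CountMatrix, DataValidationError


@dataclass
class DEParams:
    n_shortlist: int = 50
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.n_shortlist < 1:
            raise ValueError("n_shortlist must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def one_vs_rest_means(
    data: CountMatrix, cluster_cells, rest_cells=None
) -> pd.DataFrame:
    """Per-gene arithmetic means inside and outside the cluster."""
    if not data.normalized:
        raise DataValidationError("differential expression expects CPM values")
    cluster_cells = pd.Index(cluster_cells)
    if rest_cells is None:
        rest_cells = data.cell_ids.difference(cluster_cells, sort=False)
    rest_cells = pd.Index(rest_cells)
    if len(cluster_cells) == 0 or len(rest_cells) == 0:
        raise DataValidationError("both cluster and rest must be non-empty")
    mean_in = data.subset_cells(cluster_cells).values.mean(axis=1)
    mean_out = data.subset_cells(rest_cells).values.mean(axis=1)
    return pd.DataFrame({"mean_in": mean_in, "mean_out": mean_out},
                        index=data.gene_ids)


def shortlist_by_fold_change(
    means: pd.DataFrame, n_shortlist: int = 50, pseudocount: float = 0.1
) -> pd.Series:
    """Top genes by (mean_in + pc) / (mean_out + pc); ties by gene id."""
    if n_shortlist < 1:
        raise ValueError("n_shortlist must be >= 1")
    fc = (means["mean_in"] + pseudocount) / (means["mean_out"] + pseudocount)
    order = sorted(fc.index, key=lambda g: (-fc[g], str(g)))
    return fc.loc[order[:n_shortlist]].rename("fold_change")


def ks_statistic(x, y) -> float:
    """Two-sample KS statistic D = max_t |ECDF_x(t) - ECDF_y(t)|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataValidationError("KS statistic needs two non-empty samples")
    return float(scipy.stats.ks_2samp(x, y, method="asymp").statistic)


def rank_de_genes(
    data: CountMatrix, clusters: dict, params: DEParams | None = None
) -> dict[str, pd.DataFrame]:
    """Per-cluster ranked DE tables.

    ``clusters`` maps cluster name -> list of member cell ids; each
    cluster is contrasted against all remaining cells of ``data``.
    Rows are ranked by KS statistic descending, ties by fold change
    then gene id.
    """
    if params is None:
        params = DEParams()
    if not clusters:
        raise DataValidationError("no clusters to characterize")
    results: dict[str, pd.DataFrame] = {}
    for name in clusters:
        cells = pd.Index(clusters[name])
        rest = data.cell_ids.difference(cells, sort=False)
        means = one_vs_rest_means(data, cells, rest)
        fc = shortlist_by_fold_change(means, params.n_shortlist, params.pseudocount)
        in_values = data.subset_cells(cells).to_frame()
        out_values = data.subset_cells(rest).to_frame()
        rows = []
        for g in fc.index:
            d = ks_statistic(in_values.loc[g].values, out_values.loc[g].values)
            rows.append((g, means.at[g, "mean_in"], means.at[g, "mean_out"],
                         fc[g], d))
        df = pd.DataFrame(rows, columns=["gene", "mean_in", "mean_out",
                                         "fold_change", "ks_statistic"])
        df = df.sort_values(
            by=["ks_statistic", "fold_change", "gene"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        results[name] = df
    return results
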