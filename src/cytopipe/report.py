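"""Interpretation tables and figures.

Cluster-by-marker median tables drive cell-type annotation (which
populations are CD4-high, Perforin-high, ...); per-file abundance
tables expose composition shifts between samples; embedding scatter
plots color cells by cluster, sample or a marker's expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import leaves_list, linkage

from .clusterx import ClusterResult
from .dimred import Embedding
from .progression import cluster_medians

__all__ = [
    "median_expression_table",
    "abundance_table",
    "cluster_table_order",
    "render_scatter",
    "render_heatmap",
]


def _labels_of(labels) -> np.ndarray:
    return labels.labels if isinstance(labels, ClusterResult) else np.asarray(labels)


def median_expression_table(expression, labels) -> pd.DataFrame:
    """Median expression of each marker within each cluster."""
    lab = _labels_of(labels)
    values = expression.values
    if values.shape[0] != lab.shape[0]:
        raise ValueError("labels must cover all cells")
    uniq = np.unique(lab)
    rows = [np.median(values[lab == c], axis=0) for c in uniq]
    return pd.DataFrame(
        rows, index=pd.Index(uniq, name="cluster"), columns=expression.marker_names
    )


def abundance_table(labels, cell_ids) -> pd.DataFrame:
    """Percentage of each file's cells falling in each cluster.

    Rows are source files and sum to 100.
    """
    lab = _labels_of(labels)
    files = np.array([c.source_file for c in cell_ids])
    if files.shape[0] != lab.shape[0]:
        raise ValueError("cell_ids must cover all cells")
    counts = pd.crosstab(pd.Series(files, name="file"), pd.Series(lab, name="cluster"))
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


def cluster_table_order(table: pd.DataFrame) -> tuple[list, list]:
    """Row/column orderings from average-linkage hierarchical clustering."""
    def _order(mat: np.ndarray, items) -> list:
        if mat.shape[0] < 3:
            return list(items)
        tree = linkage(mat, method="average", metric="euclidean")
        return [items[i] for i in leaves_list(tree)]

    rows = _order(table.to_numpy(), list(table.index))
    cols = _order(table.to_numpy().T, list(table.columns))
    return rows, cols


def render_scatter(
    embedding: Embedding,
    out_path,
    color_by: str = "cluster",
    labels=None,
    cell_ids=None,
    marker_values: np.ndarray | None = None,
    marker_name: str = "",
) -> str:
    """Scatter plot of a 2-D embedding colored by cluster/sample/marker.

    Cluster mode annotates the numeric cluster IDs at the per-cluster
    median positions; marker mode maps expression onto a continuous
    color scale.
    """
    coords = embedding.coords
    fig, ax = plt.subplots(figsize=(6, 5.5))
    if color_by == "cluster":
        lab = _labels_of(labels)
        sc = ax.scatter(coords[:, 0], coords[:, 1], c=lab, s=4, cmap="tab20")
        med = cluster_medians(embedding, lab)
        for c, row in med.iterrows():
            ax.text(row.iloc[0], row.iloc[1], str(c), fontsize=10, weight="bold")
    elif color_by == "sample":
        files = pd.Categorical([c.source_file for c in cell_ids])
        sc = ax.scatter(coords[:, 0], coords[:, 1], c=files.codes, s=4, cmap="Set1")
    elif color_by == "marker":
        sc = ax.scatter(coords[:, 0], coords[:, 1], c=marker_values, s=4, cmap="viridis")
        fig.colorbar(sc, ax=ax, label=marker_name or "expression")
    else:
        raise ValueError("color_by must be cluster, sample or marker")
    ax.set_xlabel(f"{embedding.method}_1")
    ax.set_ylabel(f"{embedding.method}_2")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return str(out_path)


def render_heatmap(table: pd.DataFrame, out_path, title: str = "") -> str:
    """Heat map of a cluster table, rows/columns hierarchically ordered."""
    rows, cols = cluster_table_order(table)
    ordered = table.loc[rows, cols]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.45 * len(cols)), max(3, 0.35 * len(rows)))
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(cols)), [str(c) for c in cols], rotation=90, fontsize=7)
    ax.set_yticks(range(len(rows)), [str(r) for r in rows], fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return str(out_path)
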