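"""Hierarchical clustering of the regulated-protein z-score matrix.

Rows are proteins, columns are comparisons/replicates, values are
replicate z-scores in sigma units.  Missing cells are imputed to 0 sigma
(the population mean) for distance computation only.  Produces linkages,
reordered matrices, Newick dendrograms, and a diverging heat map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["ClusterResult", "cluster", "cut_rows", "to_newick", "render_heatmap"]


@dataclass
class ClusterResult:
    """Dendrograms plus the leaf-reordered z matrix."""

    matrix: pd.DataFrame          # reordered values (originals, not imputed)
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_order: list[str]          # leaf order
    col_order: list[str]
    row_labels: list[str] | None = None  # original input order
    col_labels: list[str] | None = None


def _linkage(data: np.ndarray, metric: str, method: str) -> np.ndarray:
    return hierarchy.linkage(pdist(data, metric=metric), method=method)


def cluster(
    matrix: pd.DataFrame,
    axis: str = "rows",
    metric: str = "euclidean",
    linkage: str = "average",
) -> ClusterResult:
    """Agglomeratively cluster rows, columns, or both of a z matrix.

    Raises on axes with fewer than 2 items or on all-missing rows/columns.
    Leaf order is deterministic given the input order.
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError("axis must be 'rows', 'columns' or 'both'")
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("row and column labels must be unique")
    vals = matrix.to_numpy(dtype=float)
    if np.isnan(vals).all(axis=1).any() or np.isnan(vals).all(axis=0).any():
        raise ValueError("all-missing rows/columns cannot be clustered")
    filled = np.nan_to_num(vals, nan=0.0)  # mean-impute for distances only

    row_linkage = col_linkage = None
    row_order = list(matrix.index)
    col_order = list(matrix.columns)
    if axis in ("rows", "both"):
        if matrix.shape[0] < 2:
            raise ValueError("need at least 2 rows to cluster rows")
        row_linkage = _linkage(filled, metric, linkage)
        row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_linkage)]
    if axis in ("columns", "both"):
        if matrix.shape[1] < 2:
            raise ValueError("need at least 2 columns to cluster columns")
        col_linkage = _linkage(filled.T, metric, linkage)
        col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_linkage)]

    reordered = matrix.loc[row_order, col_order]
    return ClusterResult(
        reordered, row_linkage, col_linkage, row_order, col_order,
        list(matrix.index), list(matrix.columns),
    )


def cut_rows(result: ClusterResult, n_clusters: int) -> pd.Series:
    """Flat cluster labels for the rows, indexed in original input order."""
    if result.row_linkage is None:
        raise ValueError("rows were not clustered")
    labels = hierarchy.fcluster(result.row_linkage, n_clusters, criterion="maxclust")
    return pd.Series(labels, index=result.row_labels, name="cluster")


def to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


def render_heatmap(
    result: ClusterResult,
    path: str,
    tsv_path: str | None = None,
    cmap: str = "RdBu_r",
) -> None:
    """Write a diverging heat map (symmetric scale centred at 0 sigma).

    Missing values render in grey.  The reordered matrix is also written
    as TSV next to the image (or at ``tsv_path``).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = result.matrix
    if mat.size == 0:
        raise ValueError("cannot render an empty matrix")
    vmax = float(np.nanmax(np.abs(mat.to_numpy(dtype=float))))
    vmax = vmax if vmax > 0 else 1.0

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * mat.shape[1] + 2), max(4, 0.12 * mat.shape[0] + 2))
    )
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.7")
    im = ax.imshow(
        np.ma.masked_invalid(mat.to_numpy(dtype=float)),
        aspect="auto", cmap=cm, vmin=-vmax, vmax=vmax,
    )
    ax.set_xticks(range(mat.shape[1]), labels=mat.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score (sigma)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    if tsv_path is None:
        tsv_path = str(path) + ".tsv"
    mat.to_csv(tsv_path, sep="\t", lineterminator="\n")
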