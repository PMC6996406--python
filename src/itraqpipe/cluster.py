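"""Hierarchical clustering of the protein x condition ratio matrix.

Euclidean distances between protein ratio profiles, agglomerative linkage
(average by default), and export of the leaf-ordered matrix for heat-map
display.  The matrix is a pandas DataFrame of positive median ratios with
protein accessions as the index; proteins with missing conditions must be
excluded upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Dendrogram",
    "euclidean_distances",
    "agglomerate",
    "order_matrix",
    "to_newick",
    "write_ordered_matrix",
    "plot_heatmap",
]

_LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over the matrix rows.

    ``merges`` is the scipy linkage matrix: row k merges nodes
    ``merges[k,0]`` and ``merges[k,1]`` (original leaves are 0..n-1, merged
    nodes n, n+1, ...) at Euclidean height ``merges[k,2]``.
    """

    merges: np.ndarray
    labels: tuple[str, ...]
    linkage: str

    @property
    def leaf_order(self) -> list[int]:
        return [int(i) for i in hierarchy.leaves_list(self.merges)]

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[0] < 2:
        raise ValueError("at least 2 rows required")
    if matrix.isna().any().any():
        raise ValueError("ratio matrix must not contain missing cells")
    if (matrix.to_numpy() <= 0).any():
        raise ValueError("ratios must be positive")


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of Euclidean distances between row profiles."""
    _validate_matrix(matrix)
    d = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def agglomerate(distances: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix.

    Linkage is one of average / complete / single.  Ties between equally
    close pairs are broken deterministically (lowest node index first), so
    the merge sequence is reproducible for a given row order.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    condensed = squareform(d, checks=False)
    merges = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(
        merges=merges,
        labels=tuple(str(label) for label in distances.index),
        linkage=linkage,
    )


def cluster_matrix(
    matrix: pd.DataFrame, linkage: str = "average", cluster_columns: bool = False
) -> tuple[Dendrogram, Dendrogram | None]:
    """Cluster rows (and optionally columns) of a ratio matrix."""
    rows = agglomerate(euclidean_distances(matrix), linkage)
    cols = None
    if cluster_columns:
        cols = agglomerate(euclidean_distances(matrix.T), linkage)
    return rows, cols


def order_matrix(
    matrix: pd.DataFrame,
    rows: Dendrogram,
    columns: Dendrogram | None = None,
) -> pd.DataFrame:
    """Reorder the matrix by dendrogram leaf order (rows, optionally columns)."""
    out = matrix.iloc[rows.leaf_order]
    if columns is not None:
        out = out.iloc[:, columns.leaf_order]
    return out


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize the merge tree as a newick string with branch lengths."""
    tree = hierarchy.to_tree(dendrogram.merges)
    labels = dendrogram.labels

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def write_ordered_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g", index_label="accession")


def plot_heatmap(
    ordered: pd.DataFrame, path: str | Path, cmap: str = "RdBu_r"
) -> None:
    """Convenience raster heat map of the ordered log2-ratio matrix.

    Display aid only; the tested surfaces are the ordered TSV and the
    newick merge tree.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = np.log2(ordered.to_numpy(dtype=float))
    height = max(2.0, 0.12 * ordered.shape[0])
    fig, ax = plt.subplots(figsize=(6, height))
    limit = max(1e-6, np.abs(data).max())
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-limit, vmax=limit)
    ax.set_xticks(range(ordered.shape[1]), labels=[str(c) for c in ordered.columns])
    ax.set_yticks([])
    ax.set_xlabel("condition")
    ax.set_ylabel(f"{ordered.shape[0]} proteins (dendrogram order)")
    fig.colorbar(im, ax=ax, label="log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
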