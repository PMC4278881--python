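"""Unsupervised hierarchical clustering of samples and features.

Complete-linkage agglomeration on Euclidean distances over raw log2
values, restricted to the most variable features — the structure behind
the two-way expression heat maps.  Merge heights under complete linkage
are monotone non-decreasing, which the :class:`Dendrogram` container
asserts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.cluster import hierarchy

from .io import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "top_variable_features",
    "agglomerate_complete",
    "cut_clusters",
    "heatmap_export",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: merges, their heights and the leaf order.

    ``merges[k] = (i, j)`` joins clusters ``i`` and ``j`` at
    ``heights[k]``; indices < n refer to leaves, index ``n + k`` to the
    cluster created by merge ``k`` (scipy linkage convention).
    """

    n_leaves: int
    merges: tuple[tuple[int, int], ...]
    heights: tuple[float, ...]
    leaf_order: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram on n leaves must have n-1 merges")
        if any(b < a - 1e-9 for a, b in zip(self.heights, self.heights[1:])):
            raise ValueError("complete-linkage merge heights must be non-decreasing")
        if sorted(self.leaf_order) != list(range(self.n_leaves)):
            raise ValueError("leaf order must be a permutation of the leaves")

    def to_linkage(self) -> np.ndarray:
        """Reconstruct the scipy linkage matrix."""
        sizes: dict[int, int] = {i: 1 for i in range(self.n_leaves)}
        z = np.zeros((self.n_leaves - 1, 4))
        for k, ((i, j), h) in enumerate(zip(self.merges, self.heights)):
            size = sizes[i] + sizes[j]
            sizes[self.n_leaves + k] = size
            z[k] = (i, j, h, size)
        return z


def top_variable_features(matrix: ExpressionMatrix, k: int = 20) -> list[str]:
    """IDs of the k features with the largest sample variance of log2 values.

    Ties in variance are broken lexicographically by feature ID; if k is at
    least the feature count, every feature is returned (still sorted by
    decreasing variance).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if matrix.n_features == 0:
        raise ValueError("empty expression matrix")
    variances = matrix.values.var(axis=1, ddof=1) if matrix.n_samples > 1 else np.zeros(matrix.n_features)
    order = sorted(range(matrix.n_features), key=lambda i: (-variances[i], matrix.feature_ids[i]))
    return [matrix.feature_ids[i] for i in order[: min(k, matrix.n_features)]]


def agglomerate_complete(points: np.ndarray, axis: Literal["rows", "columns"] = "rows") -> Dendrogram:
    """Complete-linkage agglomerative clustering with Euclidean distance.

    ``axis`` selects whether the rows or the columns of ``points`` are the
    items being clustered.  Inter-cluster distance is the maximum pairwise
    Euclidean distance between members.
    """
    pts = np.asarray(points, dtype=float)
    if axis == "columns":
        pts = pts.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    z = hierarchy.linkage(pts, method="complete", metric="euclidean")
    return Dendrogram(
        n_leaves=pts.shape[0],
        merges=tuple((int(r[0]), int(r[1])) for r in z),
        heights=tuple(float(r[2]) for r in z),
        leaf_order=tuple(int(i) for i in hierarchy.leaves_list(z)),
    )


def cut_clusters(dendro: Dendrogram, k: int) -> np.ndarray:
    """Assign leaves to k flat clusters by cutting the dendrogram."""
    labels = hierarchy.fcluster(dendro.to_linkage(), t=k, criterion="maxclust")
    return np.asarray(labels, dtype=int)


def heatmap_export(
    matrix: ExpressionMatrix,
    row_dendro: Dendrogram,
    col_dendro: Dendrogram,
) -> tuple[ExpressionMatrix, tuple[int, ...], tuple[int, ...]]:
    """Reorder a matrix by the dendrogram leaf orders (heat-map layout).

    Values are only permuted, never changed; the row and column orderings
    are returned alongside the reordered matrix.
    """
    if row_dendro.n_leaves != matrix.n_features or col_dendro.n_leaves != matrix.n_samples:
        raise ValueError("dendrogram sizes do not match the matrix")
    rows = list(row_dendro.leaf_order)
    cols = list(col_dendro.leaf_order)
    ordered = ExpressionMatrix(
        feature_ids=tuple(matrix.feature_ids[i] for i in rows),
        sample_ids=tuple(matrix.sample_ids[j] for j in cols),
        values=matrix.values[np.ix_(rows, cols)],
    )
    return ordered, tuple(rows), tuple(cols)
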