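"""Agglomerative hierarchical clustering with automatic linkage selection.

Four agglomeration rules are considered: single (minimum inter-cluster
distance), complete (maximum), average (UPGMA), and Ward's minimum
variance. Ward is applied in its distance-based "D2" form: the
Lance-Williams recurrence on squared dissimilarities with square-rooted
merge heights, which minimises the within-cluster error sum of squares
when the input dissimilarities are Euclidean.

The appropriate rule for a dataset is chosen automatically by the
agglomerative coefficient (Kaufman & Rousseeuw): the mean over items of
``1 - h_first / h_final``, where ``h_first`` is the height at which the
item first merges and ``h_final`` the final merge height. Values near 1
indicate strong clustering structure; the linkage with the largest
coefficient wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree as _cut_tree
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

LINKAGES = ("single", "complete", "average", "ward")

#: Tie precedence when agglomerative coefficients are equal (best first).
LINKAGE_PRECEDENCE = ("ward", "average", "complete", "single")


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative dissimilarity matrix with a zero diagonal."""

    values: np.ndarray
    item_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dissimilarity matrix contains non-finite entries")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("dissimilarity matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("dissimilarity matrix has negative entries")
        # exact symmetry for downstream condensed-form conversion
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.item_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class Dendrogram:
    """Merge tree from agglomerative clustering.

    ``merges`` is the standard (n-1) x 4 linkage matrix: the two merged
    node indices, the merge height, and the size of the new cluster.
    All four supported linkages are monotone, so heights never decrease.
    """

    merges: np.ndarray
    linkage: str
    item_ids: list[str]
    agglomerative_coefficient: float = field(init=False)

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.item_ids)
        if self.merges.shape != (n - 1, 4):
            raise ValueError(f"expected {n - 1} merges, got shape {self.merges.shape}")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-9 * max(1.0, heights.max())):
            raise ValueError(f"{self.linkage} merge heights are not monotone")
        self.agglomerative_coefficient = agglomerative_coefficient(self)

    @property
    def n(self) -> int:
        return len(self.item_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (0..k-1) from cutting the tree into k clusters."""
        if not 1 <= k <= self.n:
            raise ValueError(f"k={k} outside [1, {self.n}]")
        return _cut_tree(self.merges, n_clusters=k).ravel()


def linkage_tree(d: DissimilarityMatrix, method: str) -> Dendrogram:
    """Agglomerate a dissimilarity matrix under one linkage rule.

    Uses the Lance-Williams recurrences (scipy backend); ``ward`` is the
    D2 variant operating on the supplied dissimilarities directly.
    """
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {LINKAGES}")
    if d.n < 2:
        raise ValueError("need at least 2 items to build a tree")
    merges = _scipy_linkage(d.condensed(), method=method)
    return Dendrogram(merges, method, list(d.item_ids))


def first_merge_heights(tree: Dendrogram) -> np.ndarray:
    """Height at which each original item is first absorbed into a cluster."""
    n = tree.n
    h = np.full(n, np.nan)
    for left, right, height, _size in tree.merges:
        for node in (int(left), int(right)):
            if node < n and np.isnan(h[node]):
                h[node] = height
    return h


def agglomerative_coefficient(tree: Dendrogram) -> float:
    """Kaufman-Rousseeuw agglomerative coefficient, in [0, 1].

    Mean over items of ``1 - h_first(i) / h_final``. Larger values mean
    items join tight clusters long before the final merge, i.e. a more
    pronounced clustering structure.
    """
    h_final = tree.heights[-1]
    if h_final <= 0:
        raise ValueError("degenerate tree: all items identical (final merge height 0)")
    ac = float(np.mean(1.0 - first_merge_heights(tree) / h_final))
    return ac


def select_linkage(
    d: DissimilarityMatrix,
) -> tuple[str, Dendrogram, dict[str, float]]:
    """Fit all four linkages and keep the one with the largest coefficient.

    Returns the winning method name, its dendrogram, and the full
    coefficient table. Ties follow ``LINKAGE_PRECEDENCE``.
    """
    trees = {m: linkage_tree(d, m) for m in LINKAGES}
    ac_table = {m: t.agglomerative_coefficient for m, t in trees.items()}
    best = max(LINKAGE_PRECEDENCE, key=lambda m: (ac_table[m], -LINKAGE_PRECEDENCE.index(m)))
    logger.info(
        "linkage auto-selection: %s (AC table: %s)",
        best,
        {m: round(v, 4) for m, v in ac_table.items()},
    )
    return best, trees[best], ac_table
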