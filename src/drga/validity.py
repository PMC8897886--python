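"""Internal cluster-validity indices and the consensus rule for choosing k.

Three indices score a candidate partition of a dissimilarity matrix:

* average silhouette width (maximise; in [-1, 1]);
* Dunn's index — minimum inter-cluster distance over maximum
  intra-cluster diameter (maximise; in [0, inf));
* connectivity — for each point, penalties ``1/j`` for each of its L
  nearest neighbours (j-th nearest) assigned to a different cluster
  (minimise; 0 means every local neighbourhood is cluster-pure).

Each index votes for its best k over a candidate range; the optimal
number of clusters is declared when all three agree, or when two of the
three agree. Otherwise no optimal number is reported — a valid, if
uncommon, outcome that callers must handle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score as _sk_silhouette

from .hierarchy import Dendrogram, DissimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_NEIGHBORS = 10


def _check_labels(d: DissimilarityMatrix, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (d.n,):
        raise ValueError(f"labels shape {labels.shape} != ({d.n},)")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    return labels


def silhouette_index(d: DissimilarityMatrix, labels: np.ndarray) -> float:
    """Mean silhouette width (b - a) / max(a, b); singletons score 0."""
    labels = _check_labels(d, labels)
    return float(_sk_silhouette(d.values, labels, metric="precomputed"))


def dunn_index(d: DissimilarityMatrix, labels: np.ndarray) -> float:
    """Min inter-cluster pointwise distance / max intra-cluster diameter.

    If every cluster is a singleton the diameter is zero and the index
    is reported as ``inf`` (perfectly separated degenerate partition).
    """
    labels = _check_labels(d, labels)
    clusters = [np.flatnonzero(labels == c) for c in np.unique(labels)]
    max_diam = 0.0
    for idx in clusters:
        if len(idx) > 1:
            max_diam = max(max_diam, float(d.values[np.ix_(idx, idx)].max()))
    min_inter = np.inf
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            min_inter = min(min_inter, float(d.values[np.ix_(a, b)].min()))
    if max_diam == 0.0:
        logger.info("Dunn index: all clusters are singletons; returning inf")
        return np.inf
    return min_inter / max_diam


def connectivity_index(
    d: DissimilarityMatrix, labels: np.ndarray, n_neighbors: int = DEFAULT_NEIGHBORS
) -> float:
    """Sum of 1/j penalties for j-th nearest neighbours outside the cluster.

    Nearest-neighbour ties are broken by item order. Non-decreasing in
    ``n_neighbors`` for fixed labels.
    """
    labels = _check_labels(d, labels)
    n = d.n
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n={n}")
    total = 0.0
    for i in range(n):
        order = np.lexsort((np.arange(n), d.values[i]))
        order = order[order != i][:n_neighbors]
        ranks = np.arange(1, len(order) + 1)
        total += float(np.sum((labels[order] != labels[i]) / ranks))
    return total


@dataclass
class ConsensusDecision:
    """Outcome of the three-index vote on the number of clusters."""

    chosen_k: int | None
    votes: dict[str, int]
    agreement: str  # "3of3" | "2of3" | "none"


def consensus_k(
    d: DissimilarityMatrix,
    tree: Dendrogram,
    k_range: range | list[int] | None = None,
    n_neighbors: int = DEFAULT_NEIGHBORS,
) -> tuple[ConsensusDecision, pd.DataFrame]:
    """Score tree cuts over candidate k and apply the consensus rule.

    Each index votes for its best k (silhouette and Dunn maximise,
    connectivity minimises; ties go to the smallest k). The chosen k is
    the unanimous vote, else the k two indices agree on, else none.
    Returns the decision and the full index trace (one row per k).
    """
    if k_range is None:
        k_range = range(2, min(10, d.n - 1) + 1)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > d.n - 1:
        raise ValueError(f"k_range must lie within [2, {d.n - 1}]")
    rows = []
    for k in ks:
        labels = tree.cut(k)
        rows.append(
            {
                "k": k,
                "silhouette": silhouette_index(d, labels),
                "dunn": dunn_index(d, labels),
                "connectivity": connectivity_index(d, labels, n_neighbors),
            }
        )
    trace = pd.DataFrame(rows).set_index("k")
    votes = {
        "silhouette": _best_k(trace["silhouette"], maximise=True),
        "dunn": _best_k(trace["dunn"], maximise=True),
        "connectivity": _best_k(trace["connectivity"], maximise=False),
    }
    decision = decide_consensus(votes)
    logger.info("consensus on k: votes=%s -> %s (%s)", votes, decision.chosen_k, decision.agreement)
    return decision, trace


def _best_k(series: pd.Series, maximise: bool) -> int:
    vals = series.to_numpy(dtype=float)
    best = np.nanmax(vals) if maximise else np.nanmin(vals)
    # ties (including multiple inf) resolve to the smallest k
    mask = vals == best
    return int(series.index[np.flatnonzero(mask)[0]])


def decide_consensus(votes: dict[str, int]) -> ConsensusDecision:
    """Pure 3-of-3 / 2-of-3 / none decision from per-index votes."""
    counts = pd.Series(list(votes.values())).value_counts()
    top_k, top_n = int(counts.index[0]), int(counts.iloc[0])
    if top_n == 3:
        return ConsensusDecision(top_k, votes, "3of3")
    if top_n == 2:
        return ConsensusDecision(top_k, votes, "2of3")
    return ConsensusDecision(None, votes, "none")
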