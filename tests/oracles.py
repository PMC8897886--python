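"""Independent brute-force oracles used by the test suite.

These are deliberately naive (O(n^3) agglomeration, double loops over
points) and share no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def naive_agglomerate(dist: np.ndarray, method: str):
    """Naive agglomeration from cluster-distance definitions.

    single/complete/average recompute inter-cluster distances from the
    original matrix at every step; ward applies the distance-update
    recurrence on squared dissimilarities (the D2 form). Returns the
    merge heights and, for each cluster count k, a labelling of items.
    """
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    # ward keeps its own evolving distance table
    wdist = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    partitions = {n: {i: list(c) for i, c in clusters.items()}}
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                if method == "ward":
                    dd = wdist[(min(a, b), max(a, b))]
                else:
                    pair = [dist[i, j] for i in clusters[a] for j in clusters[b]]
                    if method == "single":
                        dd = min(pair)
                    elif method == "complete":
                        dd = max(pair)
                    elif method == "average":
                        dd = float(np.mean(pair))
                    else:
                        raise ValueError(method)
                if best is None or dd < best[0]:
                    best = (dd, a, b)
        dd, a, b = best
        heights.append(dd)
        merged = clusters[a] + clusters[b]
        if method == "ward":
            na, nb = len(clusters[a]), len(clusters[b])
            for c in clusters:
                if c in (a, b):
                    continue
                nc = len(clusters[c])
                dca = wdist[(min(a, c), max(a, c))]
                dcb = wdist[(min(b, c), max(b, c))]
                dab = wdist[(min(a, b), max(a, b))]
                new = np.sqrt(
                    ((na + nc) * dca**2 + (nb + nc) * dcb**2 - nc * dab**2)
                    / (na + nb + nc)
                )
                wdist[(min(c, next_id), max(c, next_id))] = new
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        partitions[len(clusters)] = {i: list(c) for i, c in clusters.items()}
        next_id += 1
    return np.array(heights), partitions


def partition_labels(partition: dict, n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(sorted(partition.values(), key=min)):
        labels[members] = lab
    return labels


def naive_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = np.mean([dist[i, j] for j in same])
        b = np.inf
        for c in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, np.mean([dist[i, j] for j in other]))
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def naive_dunn(dist: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    inter = np.inf
    diam = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if labels[i] == labels[j]:
                diam = max(diam, dist[i, j])
            else:
                inter = min(inter, dist[i, j])
    return np.inf if diam == 0 else inter / diam


def naive_connectivity(dist: np.ndarray, labels: np.ndarray, L: int) -> float:
    n = len(labels)
    total = 0.0
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (dist[i, j], j))
        for rank, j in enumerate(order[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def naive_ac(heights_first: np.ndarray, h_final: float) -> float:
    return float(np.mean(1.0 - heights_first / h_final))


def cox_partial_loglik(beta: float, groups, time, event) -> float:
    """Breslow partial log-likelihood for a single binary covariate.

    Exact (equals Efron) when event times are untied.
    """
    groups = np.asarray(groups, float)
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        at_risk = time >= time[i]
        ll += beta * groups[i] - np.log(np.sum(np.exp(beta * groups[at_risk])))
    return ll


def cox_brute_force_beta(groups, time, event, lo=-10.0, hi=10.0, tol=1e-10) -> float:
    """Golden-section maximization of the partial likelihood."""
    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - gr * (b - a), a + gr * (b - a)
    while abs(b - a) > tol:
        if cox_partial_loglik(c, groups, time, event) > cox_partial_loglik(
            d, groups, time, event
        ):
            b = d
        else:
            a = c
        c, d = b - gr * (b - a), a + gr * (b - a)
    return (a + b) / 2


def kendall_tau_a(x, y) -> float:
    """Exhaustive concordant/discordant pair enumeration, (C-D)/(C+D)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = d = 0
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                c += 1
            elif s < 0:
                d += 1
    return (c - d) / (c + d)


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric nonnegative matrix with zero diagonal (generic ties-free)."""
    m = rng.uniform(0.1, 10.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
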