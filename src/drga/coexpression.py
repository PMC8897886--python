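"""Co-expression module construction and module-trait association.

Genes are clustered on a correlation-derived dissimilarity (unsigned:
``1 - |r|``; signed: ``(1 - r)/2``) with the linkage rule chosen
automatically by agglomerative coefficient. The number of modules is
picked by the same three-index consensus used for patient
stratification; clusters below the minimum module size are relabelled
"grey" (unassigned), and surviving modules get conventional colour
names ordered by decreasing size.

Each module is summarised by its eigengene — the first principal
component of the standardized member expression, sign-oriented to
correlate positively with the mean member profile — which is then
correlated (Pearson) with clinical features. The top five hub genes
per module are those with the highest intramodular connectivity,
``k_in(g) = sum over same-module g' != g of |r(g, g')|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import (  # noqa: F401  (re-exported clustering surface)
    Dendrogram,
    DissimilarityMatrix,
    agglomerative_coefficient,
    linkage_tree,
    select_linkage,
)
from .io import CONTINUOUS, ClinicalTable, ExpressionMatrix
from .validity import ConsensusDecision, consensus_k

logger = logging.getLogger(__name__)

GREY = "grey"
DEFAULT_MIN_MODULE_SIZE = 30

#: Module colour names assigned by decreasing module size (WGCNA convention);
#: overflow modules are named "module<N>".
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)


@dataclass
class ModuleAssignment:
    """Gene -> module colour labels with eigengenes and hub genes."""

    labels: pd.Series  # index: gene id, value: colour ("grey" = unassigned)
    decision: ConsensusDecision | None = None
    validity_trace: pd.DataFrame | None = None
    eigengenes: pd.DataFrame | None = None  # samples x modules
    hub_genes: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return list(sizes.index)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class ModuleTraitMatrix:
    """Pearson r and p between each module eigengene and each feature."""

    r: pd.DataFrame  # modules x features
    p: pd.DataFrame


def gene_dissimilarity(expr: ExpressionMatrix, mode: str = "unsigned") -> DissimilarityMatrix:
    """Correlation-based gene-gene dissimilarity.

    unsigned: d = 1 - |r|  (co-expression regardless of direction)
    signed:   d = (1 - r)/2  (anti-correlated genes are maximally distant)
    """
    if mode not in ("unsigned", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    if expr.constant_genes:
        raise ValueError(
            f"constant gene(s) have undefined correlations: {expr.constant_genes[:10]}"
        )
    if len(expr.sample_ids) < 3:
        raise ValueError("need at least 3 samples")
    # pairwise-complete Pearson correlation over samples
    r = expr.data.T.corr(method="pearson").to_numpy()
    if mode == "unsigned":
        d = 1.0 - np.abs(r)
    else:
        d = (1.0 - r) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return DissimilarityMatrix(d, expr.gene_ids)


def detect_modules(
    tree: Dendrogram,
    d: DissimilarityMatrix,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    k_range: range | list[int] | None = None,
) -> ModuleAssignment:
    """Cut the gene tree at the consensus-optimal k and size-filter.

    Candidate cuts over ``k_range`` (default 2..min(15, n-1)) are scored
    by silhouette, Dunn, and connectivity; the 3-of-3 / 2-of-3 consensus
    picks k. Without consensus the silhouette-best k is used with a
    prominent warning. Clusters smaller than ``min_module_size`` become
    "grey"; the rest are coloured by decreasing size.
    """
    if tree.item_ids != d.item_ids:
        raise ValueError("tree and dissimilarity matrix cover different genes")
    n = d.n
    if k_range is None:
        k_range = range(2, min(15, n - 1) + 1)
    decision, trace = consensus_k(d, tree, k_range, n_neighbors=min(10, n - 1))
    if decision.chosen_k is not None:
        k = decision.chosen_k
    else:
        k = int(trace["silhouette"].idxmax())
        logger.warning(
            "no consensus on the number of modules (votes %s); falling back to the "
            "silhouette-best k=%d", decision.votes, k,
        )
    raw = tree.cut(k)
    labels = _colorize(raw, d.item_ids, min_module_size)
    return ModuleAssignment(labels, decision, trace)


def _colorize(raw: np.ndarray, ids: Sequence[str], min_size: int) -> pd.Series:
    counts = pd.Series(raw).value_counts()
    colors: dict[int, str] = {}
    next_color = 0
    for cluster, size in counts.items():
        if size < min_size:
            colors[cluster] = GREY
        else:
            colors[cluster] = (
                MODULE_COLORS[next_color]
                if next_color < len(MODULE_COLORS)
                else f"module{next_color + 1}"
            )
            next_color += 1
    if next_color == 0:
        logger.warning("no cluster reached min_module_size=%d; all genes are grey", min_size)
    return pd.Series([colors[c] for c in raw], index=list(ids), name="module")


def module_eigengene(expr: ExpressionMatrix, members: Sequence[str]) -> pd.Series:
    """First principal component of the standardized member expression.

    Member genes are z-scored across samples; the leading left singular
    vector of the samples x genes z-matrix is rescaled to zero mean and
    unit variance and sign-oriented to correlate positively with the
    mean member profile. A single-gene module therefore returns that
    gene's standardized profile exactly.
    """
    members = list(members)
    if not members:
        raise ValueError("module has no members")
    sub = expr.data.loc[members].to_numpy(dtype=float)  # genes x samples
    sd = sub.std(axis=1, ddof=1)
    if np.all(sd == 0):
        raise ValueError("all member genes are constant")
    keep = sd > 0
    z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    u, _s, _vt = np.linalg.svd(z.T, full_matrices=False)
    pc = u[:, 0]
    mean_profile = z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    pc = (pc - pc.mean()) / pc.std(ddof=1)
    return pd.Series(pc, index=expr.sample_ids)


def compute_eigengenes(expr: ExpressionMatrix, assignment: ModuleAssignment) -> pd.DataFrame:
    """Eigengene per non-grey module, stored on the assignment and returned."""
    eig = {m: module_eigengene(expr, assignment.members(m)) for m in assignment.modules}
    table = pd.DataFrame(eig)
    assignment.eigengenes = table
    return table


def module_trait_matrix(
    eigengenes: pd.DataFrame, clinical: ClinicalTable, features: Sequence[str]
) -> ModuleTraitMatrix:
    """Pearson r and p between every module eigengene and every feature."""
    for f in features:
        if clinical.feature_types.get(f) != CONTINUOUS:
            raise ValueError(f"feature {f!r} is not continuous")
    r = pd.DataFrame(index=eigengenes.columns, columns=list(features), dtype=float)
    p = r.copy()
    for f in features:
        y = clinical.data[f].to_numpy(dtype=float)
        for m in eigengenes.columns:
            x = eigengenes[m].to_numpy(dtype=float)
            mask = np.isfinite(x) & np.isfinite(y)
            res = stats.pearsonr(x[mask], y[mask])
            r.loc[m, f] = res.statistic
            p.loc[m, f] = res.pvalue
    return ModuleTraitMatrix(r, p)


def hub_genes(
    expr: ExpressionMatrix, assignment: ModuleAssignment, top_n: int = 5
) -> dict[str, pd.DataFrame]:
    """Top-``top_n`` genes per module by intramodular connectivity.

    Connectivity of gene g is the sum of |Pearson r| to every other
    gene in its module. Ties break lexicographically on the gene id;
    modules smaller than ``top_n`` return every member (logged).
    """
    out: dict[str, pd.DataFrame] = {}
    for module in assignment.modules:
        members = assignment.members(module)
        sub = expr.data.loc[members]
        corr = sub.T.corr(method="pearson").abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        k_in = corr.sum(axis=1)
        table = pd.DataFrame({"gene": members, "k_in": k_in})
        table = table.sort_values(["k_in", "gene"], ascending=[False, True], kind="stable")
        if len(table) < top_n:
            logger.warning(
                "module %s has only %d member(s); returning all as hubs", module, len(table)
            )
        table = table.head(top_n).reset_index(drop=True)
        table.insert(0, "rank", np.arange(1, len(table) + 1))
        table.insert(0, "module", module)
        out[module] = table
    assignment.hub_genes = out
    return out


# ---------------------------------------------------------------------------
# report writers


def write_module_assignment(assignment: ModuleAssignment, path: str | Path) -> None:
    df = assignment.labels.rename_axis("gene").reset_index()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_hub_genes(hubs: dict[str, pd.DataFrame], path: str | Path) -> None:
    if hubs:
        table = pd.concat(hubs.values(), ignore_index=True)
    else:
        table = pd.DataFrame(columns=["module", "rank", "gene", "k_in"])
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def plot_module_trait(mtm: ModuleTraitMatrix, path: str | Path) -> None:
    """Heatmap of module-trait correlations with r and p printed per cell."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = mtm.r.astype(float)
    fig, ax = plt.subplots(
        figsize=(1.6 * max(3, r.shape[1]), 0.7 * max(3, r.shape[0]) + 1.5)
    )
    im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(r.shape[0]), r.index)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            ax.text(
                j, i, f"{r.iloc[i, j]:.2f}\n({mtm.p.iloc[i, j]:.2g})",
                ha="center", va="center", fontsize=8,
            )
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Module–trait relationships")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
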