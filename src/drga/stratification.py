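"""Patient stratification over driver-gene profiles.

Samples are clustered on Euclidean distance in per-gene standardized
driver expression space, with the linkage rule chosen by agglomerative
coefficient and the number of subgroups by the silhouette/Dunn/
connectivity consensus. Identified subgroups are then compared on
survival (univariate Cox, hazard ratio with 95% CI) and on clinical
features, where the statistical test is dispatched automatically:

* continuous + Shapiro-Wilk accepts normality in every subgroup
  -> Welch t-test (2 groups) or one-way ANOVA (>2), summaries mean (SD);
* continuous + normality rejected -> Mann-Whitney U or Kruskal-Wallis,
  summaries median [IQR];
* categorical (including ordinal-looking numerics with few levels)
  -> chi-square, switching to Fisher's exact for 2x2 tables with any
  expected count below 5, summaries counts (%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .association import SurvivalAssociation, cox_univariate
from .hierarchy import DissimilarityMatrix, select_linkage
from .io import CATEGORICAL, AlignedDataset, ClinicalTable
from .validity import (  # noqa: F401  (re-exported validity surface)
    ConsensusDecision,
    connectivity_index,
    consensus_k,
    dunn_index,
    silhouette_index,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class TestChoice:
    """Record of the automatic test dispatch for one clinical feature."""

    feature: str
    branch: str  # continuous-normal | continuous-non-normal | categorical
    test: str
    summary_style: str  # mean(SD) | median[IQR] | counts(%)


@dataclass
class SubgroupResult:
    """Subgroup labels plus the survival and clinical comparisons."""

    labels: pd.Series | None  # sample -> subgroup id (1..k), None if no consensus
    decision: ConsensusDecision
    validity_trace: pd.DataFrame
    linkage: str
    ac_table: dict[str, float]
    survival: list[SurvivalAssociation] = field(default_factory=list)
    clinical_comparison: pd.DataFrame | None = None

    @property
    def found(self) -> bool:
        return self.labels is not None


def sample_dissimilarity(driver_expr) -> DissimilarityMatrix:
    """Euclidean sample-sample distance over standardized driver expression.

    Each driver gene is z-scored across samples first, so the distance
    is invariant to per-gene affine rescaling of the raw expression.
    Constant genes (and genes with missing values) are dropped with a
    warning; at least two usable genes and four samples are required.
    """
    data = driver_expr.data
    if data.shape[1] < 4:
        raise ValueError("need at least 4 samples to stratify")
    vals = data.to_numpy(dtype=float)
    usable = np.isfinite(vals).all(axis=1) & (np.nanstd(vals, axis=1) > 0)
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.warning(
            "dropping %d driver gene(s) that are constant or have missing values "
            "before sample clustering", n_dropped,
        )
    if usable.sum() < 2:
        raise ValueError("fewer than 2 usable driver genes for sample clustering")
    z = vals[usable]
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    dist = squareform(pdist(z.T, metric="euclidean"))
    return DissimilarityMatrix(dist, list(data.columns))


def stratify(
    data: AlignedDataset,
    k_range: range | list[int] | None = None,
    n_neighbors: int = 10,
) -> SubgroupResult:
    """Cluster samples and pick the consensus number of subgroups.

    Subgroup ids are 1..k ordered by decreasing size. When the three
    indices reach no consensus, labels are withheld and only the
    validity traces are returned (``result.found`` is False).
    """
    d = sample_dissimilarity(data.driver_expression())
    method, tree, ac_table = select_linkage(d)
    if k_range is None:
        k_range = range(2, min(10, d.n - 1) + 1)
    decision, trace = consensus_k(d, tree, k_range, n_neighbors=min(n_neighbors, d.n - 1))
    if decision.chosen_k is None:
        logger.warning("no optimal number of subgroups found (votes %s)", decision.votes)
        return SubgroupResult(None, decision, trace, method, ac_table)
    raw = tree.cut(decision.chosen_k)
    order = pd.Series(raw).value_counts().index  # largest subgroup first
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=data.sample_ids, name="subgroup")
    result = SubgroupResult(labels, decision, trace, method, ac_table)
    if data.clinical.has_survival():
        try:
            result.survival = compare_survival(labels, data.clinical)
        except ValueError as exc:
            logger.warning("subgroup survival comparison skipped: %s", exc)
    return result


def compare_survival(labels: pd.Series, clinical: ClinicalTable) -> list[SurvivalAssociation]:
    """Univariate Cox comparison between subgroups.

    With two subgroups a single hazard ratio (subgroup 2 vs subgroup 1)
    is returned. With k > 2, each smaller subgroup is contrasted
    against the largest (subgroup 1) as reference, one Cox fit per
    contrast.
    """
    if not clinical.has_survival():
        raise ValueError("clinical table carries no survival columns")
    lab = labels.loc[clinical.sample_ids]
    time = clinical.survival_time.to_numpy(dtype=float)
    event = clinical.survival_event.to_numpy(dtype=float)
    groups = sorted(lab.unique())
    out = []
    for g in groups[1:]:
        mask = lab.isin([groups[0], g]).to_numpy()
        res = cox_univariate((lab[mask] == g).astype(int).to_numpy(), time[mask], event[mask])
        res.gene_id = f"subgroup {g} vs {groups[0]}"
        out.append(res)
    return out


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston's algorithm); 3 <= n <= 5000."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _is_normal(groups: list[np.ndarray], alpha: float = ALPHA) -> bool:
    """Normal branch iff Shapiro-Wilk accepts in every subgroup.

    Subgroups too small to test (n < 3) force the non-normal branch —
    the conservative choice when normality cannot be assessed.
    """
    for g in groups:
        if len(g) < 3:
            return False
        _w, p = shapiro_wilk(g)
        if p <= alpha:
            return False
    return True


def dispatch_test(
    feature: str, values: pd.Series, labels: pd.Series, declared_type: str
) -> tuple[TestChoice, float, list[str]]:
    """Choose and run the appropriate between-subgroup test for one feature.

    Returns the dispatch record, the p-value, and per-subgroup summary
    strings in subgroup-id order.
    """
    groups_ids = sorted(labels.unique())
    if declared_type == CATEGORICAL:
        table = pd.crosstab(values, labels)
        obs = table.to_numpy(dtype=float)
        if obs.shape[0] < 2:
            raise ValueError(f"feature {feature!r} has a single observed level")
        expected = stats.contingency.expected_freq(obs)
        if obs.shape == (2, 2) and (expected < 5).any():
            test = "fisher"
            _odds, p = stats.fisher_exact(obs)
        else:
            test = "chi-square"
            chi = stats.chi2_contingency(obs, correction=False)
            p = chi.pvalue
        summaries = []
        for g in groups_ids:
            col = table[g] if g in table.columns else pd.Series(0, index=table.index)
            total = int(col.sum())
            parts = [
                f"{level}: {int(cnt)} ({100 * cnt / total:.1f}%)" if total else f"{level}: 0"
                for level, cnt in col.items()
            ]
            summaries.append("; ".join(parts))
        choice = TestChoice(feature, "categorical", test, "counts(%)")
        return choice, float(p), summaries

    per_group = [
        values[labels == g].astype(float).dropna().to_numpy() for g in groups_ids
    ]
    if any(len(g) == 0 for g in per_group):
        raise ValueError(f"feature {feature!r} unobserved in some subgroup")
    if _is_normal(per_group):
        if len(per_group) == 2:
            test, branch = "welch-t", "continuous-normal"
            p = stats.ttest_ind(per_group[0], per_group[1], equal_var=False).pvalue
        else:
            test, branch = "anova", "continuous-normal"
            p = stats.f_oneway(*per_group).pvalue
        summaries = [f"{g.mean():.3g} ({g.std(ddof=1):.3g})" for g in per_group]
        style = "mean(SD)"
    else:
        if len(per_group) == 2:
            test, branch = "mann-whitney", "continuous-non-normal"
            p = stats.mannwhitneyu(per_group[0], per_group[1], alternative="two-sided").pvalue
        else:
            test, branch = "kruskal-wallis", "continuous-non-normal"
            p = stats.kruskal(*per_group).pvalue
        summaries = [
            f"{np.median(g):.3g} [{np.percentile(g, 25):.3g};{np.percentile(g, 75):.3g}]"
            for g in per_group
        ]
        style = "median[IQR]"
    return TestChoice(feature, branch, test, style), float(p), summaries


def compare_clinical(
    labels: pd.Series, clinical: ClinicalTable, features: Sequence[str]
) -> pd.DataFrame:
    """Compare subgroups on each feature with automatic test dispatch.

    Returns one row per feature: the branch taken, the test used, a
    summary per subgroup, and the p-value. Degenerate features are
    skipped with a warning.
    """
    lab = labels.loc[clinical.sample_ids]
    group_ids = sorted(lab.unique())
    rows = []
    for feature in features:
        if feature not in clinical.feature_types:
            raise ValueError(f"unknown clinical feature {feature!r}")
        values = clinical.data[feature]
        if values.dropna().nunique() < 2:
            logger.warning("feature %r has a single observed value; skipped", feature)
            continue
        try:
            choice, p, summaries = dispatch_test(
                feature, values, lab, clinical.feature_types[feature]
            )
        except ValueError as exc:
            logger.warning("feature %r skipped: %s", feature, exc)
            continue
        row = {"feature": feature, "branch": choice.branch, "test": choice.test,
               "summary_style": choice.summary_style}
        for g, s in zip(group_ids, summaries):
            row[f"subgroup_{g} (N={int((lab == g).sum())})"] = s
        row["p"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report writers


def write_subgroups(result: SubgroupResult, path: str | Path) -> None:
    if result.labels is None:
        raise ValueError("no subgroup labels to write (no consensus)")
    result.labels.rename_axis("sample").reset_index().to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_clinical_comparison(table: pd.DataFrame, path_csv: str | Path) -> None:
    """CSV (canonical, diff-friendly) plus an xlsx twin alongside."""
    path_csv = Path(path_csv)
    table.to_csv(path_csv, index=False, float_format="%.6g", lineterminator="\n")
    table.to_excel(path_csv.with_suffix(".xlsx"), index=False)


def plot_validity_trace(trace: pd.DataFrame, path: str | Path) -> None:
    """Three trace plots (silhouette, Dunn, connectivity) over candidate k."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, col, goal in zip(
        axes, ["silhouette", "dunn", "connectivity"], ["maximise", "maximise", "minimise"]
    ):
        vals = trace[col].replace(np.inf, np.nan)
        ax.plot(trace.index, vals, "o-", color="black")
        ax.set_xlabel("number of subgroups k")
        ax.set_title(f"{col} ({goal})")
        ax.set_xticks(list(trace.index))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_expression_heatmap(driver_expr, labels: pd.Series, path: str | Path) -> None:
    """Driver-gene expression heatmap with a subgroup colour bar."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = driver_expr.data
    vals = data.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd
    order = np.argsort(labels.loc[data.columns].to_numpy(), kind="stable")
    z = z[:, order]
    lab_sorted = labels.loc[data.columns].to_numpy()[order]

    fig, (ax_bar, ax_hm) = plt.subplots(
        2, 1, figsize=(8, 6), height_ratios=[1, 15], sharex=True
    )
    cmap = plt.get_cmap("tab10")
    ax_bar.imshow(lab_sorted[None, :], aspect="auto", cmap=cmap)
    ax_bar.set_yticks([])
    ax_bar.set_title("samples coloured by subgroup")
    im = ax_hm.imshow(z, aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax_hm.set_ylabel("driver genes")
    ax_hm.set_xlabel("samples (grouped by subgroup)")
    fig.colorbar(im, ax=ax_hm, label="z-scored expression")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
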