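"""Per-gene association screening against clinical features and survival.

Two screens are provided:

* ``associate_features`` — correlation (Pearson, Spearman, or Kendall)
  between each driver gene's expression and each continuous clinical
  feature, with Benjamini-Hochberg adjustment within each feature.
* ``survival_screen`` — each gene's expression is dichotomized into
  up/down groups at the mean or median, a univariate Cox proportional
  hazards model is fitted on the group indicator (hazard ratio with
  Wald 95% CI, p-value from the log-rank/score test), and q-values are
  obtained by Benjamini-Hochberg across all genes.

All tests are two-sided; a gene/feature pair or a gene is called
significant at q <= 0.05. Kendall's coefficient is the tau of
concordant-vs-discordant pairs, (C - D)/(C + D); with ties present the
tie-corrected tau-b is computed instead and the deviation is logged.
Correlation p-values use the t approximation with n-2 df for Pearson
and Spearman; Kendall uses exact enumeration for n <= 10 without ties
and the normal approximation otherwise. Cox ties are handled with the
Efron approximation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io import CONTINUOUS, AlignedDataset

logger = logging.getLogger(__name__)

ALPHA = 0.05
METHODS = ("pearson", "spearman", "kendall")
SPLIT_RULES = ("mean", "median")


@dataclass
class CorrelationResult:
    r: float
    n_pairs: int
    p_value: float
    method: str


@dataclass
class SurvivalAssociation:
    gene_id: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float
    n_used: int
    split_rule: str

    @property
    def significant(self) -> bool:
        return self.q_value <= ALPHA


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Correlation between two vectors on pairwise-complete observations.

    Returns NaN r/p (with a warning) when exactly one vector is
    constant; raises when both are constant or fewer than 3 complete
    pairs remain.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    xs, ys = _pairwise_complete(x, y)
    n = len(xs)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    x_const = np.ptp(xs) == 0
    y_const = np.ptp(ys) == 0
    if x_const and y_const:
        raise ValueError("undefined correlation: both vectors constant")
    if x_const or y_const:
        logger.warning("one vector is constant; correlation undefined (NaN)")
        return CorrelationResult(np.nan, n, np.nan, method)
    if method == "pearson":
        res = stats.pearsonr(xs, ys)
        r, p = float(res.statistic), float(res.pvalue)
    elif method == "spearman":
        r, p = stats.spearmanr(xs, ys)
        r, p = float(r), float(p)
    else:
        has_ties = len(np.unique(xs)) < n or len(np.unique(ys)) < n
        if has_ties:
            logger.info("ties present: reporting tie-corrected Kendall tau-b")
        how = "asymptotic" if (has_ties or n > 10) else "exact"
        res = stats.kendalltau(xs, ys, method=how)
        r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(r, n, p, method)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and within [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def dichotomize(gene_expr, rule: str = "median") -> np.ndarray:
    """Split samples into down (0) / up (1) groups at the mean or median.

    A sample is "up" when its expression strictly exceeds the
    threshold. Raises if the vector is constant or either group would
    be empty; missing values are not allowed here (mask first).
    """
    if rule not in SPLIT_RULES:
        raise ValueError(f"unknown split rule {rule!r}; choose from {SPLIT_RULES}")
    x = np.asarray(gene_expr, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("dichotomize requires finite values; mask missing data first")
    if np.ptp(x) == 0:
        raise ValueError("cannot dichotomize a constant vector")
    threshold = float(np.mean(x)) if rule == "mean" else float(np.median(x))
    groups = (x > threshold).astype(int)
    if groups.sum() in (0, len(x)):
        raise ValueError(f"{rule} split leaves one expression group empty")
    return groups


def cox_univariate(groups, time, event) -> SurvivalAssociation:
    """Univariate Cox PH fit on a binary group indicator.

    Hazard ratio of group 1 ("up") versus group 0 with Wald 95% CI on
    the log scale; the p-value comes from the log-rank (score) test.
    Samples with missing time or event are dropped first.
    """
    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if not (len(groups) == len(time) == len(event)):
        raise ValueError("groups, time, event must have equal length")
    mask = np.isfinite(time) & np.isfinite(event)
    groups, time, event = groups[mask], time[mask], event[mask]
    if len(np.unique(groups)) < 2:
        raise ValueError("one group is empty after removing missing survival")
    if event.sum() == 0:
        raise ValueError("no events observed; Cox model is undefined")
    df = pd.DataFrame({"time": time, "event": event.astype(int), "group": groups})
    fitter = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # tight Newton tolerance: flat partial likelihoods at small n otherwise
        # stop a few 1e-4 short of the MLE
        fitter.fit(df, duration_col="time", event_col="event",
                   fit_options={"precision": 1e-10})
    beta = float(fitter.params_["group"])
    se = float(fitter.standard_errors_["group"])
    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])
    with np.errstate(over="ignore"):  # separated groups give hr/ci_high = inf
        hr, lo, hi = np.exp(
            [beta, beta - 1.959963984540054 * se, beta + 1.959963984540054 * se]
        )
    return SurvivalAssociation(
        gene_id="",
        hr=float(hr),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(lr.p_value),
        q_value=np.nan,
        n_used=len(df),
        split_rule="",
    )


def associate_features(
    data: AlignedDataset, features: list[str], method: str = "pearson"
) -> pd.DataFrame:
    """Correlate each driver gene with each continuous clinical feature.

    Returns a long table (gene, feature, r, n, p, q, significant) with
    BH adjustment applied within each feature's family of genes.
    Constant genes yield NaN rows and are excluded from the family.
    """
    for f in features:
        if f not in data.clinical.feature_types:
            raise ValueError(f"unknown clinical feature {f!r}")
        if data.clinical.feature_types[f] != CONTINUOUS:
            raise ValueError(
                f"feature {f!r} is categorical; correlation is undefined — use the "
                "subgroup clinical comparison instead"
            )
    rows = []
    expr = data.driver_expression()
    for feature in features:
        y = data.clinical.data[feature].to_numpy(dtype=float)
        for gene in data.driver_genes:
            x = expr.data.loc[gene].to_numpy(dtype=float)
            try:
                res = correlate(x, y, method)
            except ValueError as exc:
                logger.warning("gene %s vs %s: %s", gene, feature, exc)
                res = CorrelationResult(np.nan, int(np.isfinite(x).sum()), np.nan, method)
            rows.append(
                {"gene": gene, "feature": feature, "r": res.r, "n": res.n_pairs,
                 "p": res.p_value}
            )
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for feature in features:
        fam = table["feature"] == feature
        ok = fam & table["p"].notna()
        if ok.any():
            table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    table["significant"] = table["q"] <= ALPHA
    return table


def survival_screen(data: AlignedDataset, rule: str = "median") -> list[SurvivalAssociation]:
    """Dichotomized univariate Cox screen over all driver genes.

    Each gene is split into up/down expression groups, a Cox model is
    fitted, and q-values are BH-adjusted across the genes; q <= 0.05
    flags a gene as survival-associated.
    """
    clin = data.clinical
    if not clin.has_survival():
        raise ValueError("clinical table carries no survival columns")
    expr = data.driver_expression()
    time = clin.survival_time.to_numpy(dtype=float)
    event = clin.survival_event.to_numpy(dtype=float)
    results: list[SurvivalAssociation] = []
    for gene in data.driver_genes:
        x = expr.data.loc[gene].to_numpy(dtype=float)
        mask = np.isfinite(x)
        try:
            groups = np.full(len(x), -1)
            groups[mask] = dichotomize(x[mask], rule)
            keep = groups >= 0
            res = cox_univariate(groups[keep], time[keep], event[keep])
        except ValueError as exc:
            logger.warning("survival screen skipped gene %s: %s", gene, exc)
            continue
        res.gene_id = gene
        res.split_rule = rule
        results.append(res)
    if results:
        q = bh_adjust([r.p_value for r in results])
        for r, qi in zip(results, q):
            r.q_value = float(qi)
    return results


# ---------------------------------------------------------------------------
# report writers


def write_associations(table: pd.DataFrame, path: str | Path) -> None:
    out = table[["gene", "feature", "r", "n", "p", "q", "significant"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_survival(results: list[SurvivalAssociation], path: str | Path) -> None:
    rows = [
        {"gene": r.gene_id, "hr": r.hr, "ci_low": r.ci_low, "ci_high": r.ci_high,
         "p": r.p_value, "q": r.q_value, "n": r.n_used, "split_rule": r.split_rule,
         "significant": r.significant}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g",
                              lineterminator="\n")
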