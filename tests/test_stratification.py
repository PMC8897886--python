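import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from drga.io import AlignedDataset, ClinicalTable, ExpressionMatrix
from drga.simulate import make_clinical, make_subgrouped_expression, make_survival
from drga.stratification import (
    compare_clinical,
    compare_survival,
    dispatch_test,
    sample_dissimilarity,
    shapiro_wilk,
    stratify,
)


def _expr(rows):
    rows = np.asarray(rows, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])],
                     columns=[f"s{i}" for i in range(rows.shape[1])])
    )


def _aligned(expr, groups, seed=0, log_hr=np.log(2), censor_rate=0.02, specs=None):
    groups = pd.Series(np.asarray(groups), index=expr.sample_ids)
    surv = make_survival(groups, log_hr=log_hr, censor_rate=censor_rate, seed=seed)
    specs = specs or [{"name": "age", "dist": "normal", "mean": 50, "sd": 5}]
    clin, _ = make_clinical(groups, specs, seed=seed)
    clin = ClinicalTable(
        clin.data, clin.feature_types,
        pd.Series(surv["time"].to_numpy(), index=expr.sample_ids),
        pd.Series(surv["event"].to_numpy(dtype=float), index=expr.sample_ids),
    )
    return AlignedDataset(expr, clin, expr.gene_ids)


class TestSampleDissimilarity:
    def test_identical_samples_zero_distance(self, rng):
        base = rng.normal(size=(5, 6))
        base[:, 1] = base[:, 0]
        d = sample_dissimilarity(_expr(base))
        assert d.values[0, 1] == pytest.approx(0, abs=1e-10)

    def test_matches_zscore_euclidean_oracle(self, rng):
        raw = rng.normal(size=(6, 10))
        d = sample_dissimilarity(_expr(raw))
        z = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, ddof=1, keepdims=True)
        expected = squareform(pdist(z.T))
        np.testing.assert_allclose(d.values, expected, atol=1e-10)

    def test_per_gene_affine_invariance(self, rng):
        raw = rng.normal(size=(5, 8))
        scale = rng.uniform(0.5, 4, size=(5, 1))
        shift = rng.normal(size=(5, 1))
        d0 = sample_dissimilarity(_expr(raw))
        d1 = sample_dissimilarity(_expr(raw * scale + shift))
        np.testing.assert_allclose(d0.values, d1.values, atol=1e-10)

    def test_constant_gene_dropped_then_error(self, rng):
        raw = rng.normal(size=(3, 6))
        raw[0] = 1.0
        d = sample_dissimilarity(_expr(raw))  # one dropped, two remain
        assert d.n == 6
        all_const = np.ones((2, 6))
        with pytest.raises(ValueError, match="usable"):
            sample_dissimilarity(_expr(all_const))

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="4 samples"):
            sample_dissimilarity(_expr(rng.normal(size=(5, 3))))


class TestStratify:
    def test_two_planted_groups_fully_recovered(self):
        expr, truth = make_subgrouped_expression(
            n_genes=20, n_samples=60, k_groups=2, shift_sd=2.0, seed=13
        )
        data = _aligned(expr, truth.subgroup_labels.to_numpy(), seed=13)
        result = stratify(data, k_range=range(2, 8))
        assert result.found and result.decision.chosen_k == 2
        ari = adjusted_rand_score(
            truth.subgroup_labels.to_numpy(), result.labels.to_numpy()
        )
        assert ari == 1.0

    def test_three_planted_groups(self):
        expr, truth = make_subgrouped_expression(
            n_genes=20, n_samples=90, k_groups=3, shift_sd=3.0, seed=21
        )
        data = _aligned(expr, (truth.subgroup_labels.to_numpy() == 2).astype(int), seed=21)
        result = stratify(data, k_range=range(2, 8))
        assert result.found and result.decision.chosen_k == 3

    def test_subgroup_ids_ordered_by_size(self):
        expr, truth = make_subgrouped_expression(
            n_genes=15, n_samples=50, k_groups=2, shift_sd=3.0, seed=2
        )
        # unbalance the groups: drop 10 samples from group 1
        drop = truth.subgroup_labels[truth.subgroup_labels == 1].index[:10]
        keep = [s for s in expr.sample_ids if s not in set(drop)]
        sub = ExpressionMatrix(expr.data[keep].copy())
        data = _aligned(sub, truth.subgroup_labels.loc[keep].to_numpy(), seed=2)
        result = stratify(data, k_range=range(2, 6))
        sizes = result.labels.value_counts()
        assert list(sizes.index) == sorted(sizes.index)  # 1 is largest

    def test_no_consensus_reports_traces_without_labels(self, monkeypatch):
        from drga import stratification as strat
        from drga.validity import ConsensusDecision

        expr, truth = make_subgrouped_expression(seed=5)
        data = _aligned(expr, truth.subgroup_labels.to_numpy(), seed=5)

        def fake_consensus(d, tree, k_range, n_neighbors=10):
            import drga.validity as v

            _dec, trace = v.consensus_k(d, tree, k_range, n_neighbors)
            return ConsensusDecision(None, {"silhouette": 2, "dunn": 3,
                                            "connectivity": 4}, "none"), trace

        monkeypatch.setattr(strat, "consensus_k", fake_consensus)
        result = stratify(data, k_range=range(2, 5))
        assert not result.found and result.labels is None
        assert result.validity_trace is not None


class TestCompareSurvival:
    def test_identical_survival_hr_one(self):
        t = np.tile([1.0, 2, 3, 4, 5], 2)
        e = np.tile([1.0, 1, 0, 1, 1], 2)
        samples = [f"s{i}" for i in range(10)]
        clin = ClinicalTable(
            pd.DataFrame({"age": np.arange(10.0)}, index=samples),
            {"age": "continuous"},
            pd.Series(t, index=samples), pd.Series(e, index=samples),
        )
        labels = pd.Series([1] * 5 + [2] * 5, index=samples)
        res = compare_survival(labels, clin)
        assert len(res) == 1
        assert res[0].hr == pytest.approx(1.0, abs=1e-5)

    def test_three_groups_reference_contrasts(self, rng):
        samples = [f"s{i}" for i in range(60)]
        clin = ClinicalTable(
            pd.DataFrame({"age": rng.normal(size=60)}, index=samples),
            {"age": "continuous"},
            pd.Series(rng.exponential(5, 60), index=samples),
            pd.Series(np.ones(60), index=samples),
        )
        labels = pd.Series([1] * 30 + [2] * 20 + [3] * 10, index=samples)
        res = compare_survival(labels, clin)
        assert [r.gene_id for r in res] == ["subgroup 2 vs 1", "subgroup 3 vs 1"]

    def test_no_events_error(self):
        samples = [f"s{i}" for i in range(6)]
        clin = ClinicalTable(
            pd.DataFrame({"age": np.arange(6.0)}, index=samples),
            {"age": "continuous"},
            pd.Series(np.arange(1.0, 7.0), index=samples),
            pd.Series(np.zeros(6), index=samples),
        )
        with pytest.raises(ValueError, match="events"):
            compare_survival(pd.Series([1, 1, 1, 2, 2, 2], index=samples), clin)


class TestShapiroWilk:
    def test_n3_w_is_one(self):
        w, _p = shapiro_wilk([1.0, 2.0, 3.0])
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_range_errors(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk(np.zeros(5001))

    def test_power_against_exponential(self, rng):
        rejections = sum(
            shapiro_wilk(rng.exponential(size=100))[1] <= 0.05 for _ in range(50)
        )
        assert rejections >= 48


class TestDispatch:
    def _labels(self, n_per_group, k=2):
        return pd.Series(
            np.repeat(np.arange(1, k + 1), n_per_group),
            index=[f"s{i}" for i in range(n_per_group * k)],
        )

    def test_normal_feature_welch_t(self):
        labels = self._labels(50)
        # seed chosen so Shapiro-Wilk clearly accepts normality in both subgroups
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.normal(10, 2, 100), index=labels.index)
        choice, p, summaries = dispatch_test("f", vals, labels, "continuous")
        assert choice.test == "welch-t" and choice.summary_style == "mean(SD)"
        a, b = vals[labels == 1], vals[labels == 2]
        assert p == pytest.approx(stats.ttest_ind(a, b, equal_var=False).pvalue)

    def test_exponential_feature_mann_whitney(self, rng):
        labels = self._labels(100)
        vals = pd.Series(rng.exponential(size=200), index=labels.index)
        choice, p, _ = dispatch_test("f", vals, labels, "continuous")
        assert choice.test == "mann-whitney" and choice.summary_style == "median[IQR]"
        a, b = vals[labels == 1], vals[labels == 2]
        assert p == pytest.approx(
            stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        )

    def test_three_group_normal_anova(self):
        labels = self._labels(40, k=3)
        rng = np.random.default_rng(2)
        vals = pd.Series(rng.normal(size=120), index=labels.index)
        choice, p, _ = dispatch_test("f", vals, labels, "continuous")
        assert choice.test == "anova"
        groups = [vals[labels == g] for g in (1, 2, 3)]
        assert p == pytest.approx(stats.f_oneway(*groups).pvalue)

    def test_three_group_skewed_kruskal(self, rng):
        labels = self._labels(60, k=3)
        vals = pd.Series(rng.exponential(size=180), index=labels.index)
        choice, p, _ = dispatch_test("f", vals, labels, "continuous")
        assert choice.test == "kruskal-wallis"

    def test_small_expected_counts_fisher(self):
        # 2x2 table [[1, 9], [8, 2]]: expected counts < 5 everywhere
        labels = self._labels(10)
        vals = pd.Series(["A"] * 1 + ["B"] * 9 + ["A"] * 8 + ["B"] * 2,
                         index=labels.index)
        choice, p, _ = dispatch_test("f", vals, labels, "categorical")
        assert choice.test == "fisher"
        assert p == pytest.approx(
            stats.fisher_exact(np.array([[1, 8], [9, 2]]))[1]
        )

    def test_large_table_chi_square(self, rng):
        labels = self._labels(100)
        vals = pd.Series(rng.choice(["A", "B", "C"], size=200), index=labels.index)
        choice, p, _ = dispatch_test("f", vals, labels, "categorical")
        assert choice.test == "chi-square"
        table = pd.crosstab(vals, labels).to_numpy()
        assert p == pytest.approx(stats.chi2_contingency(table, correction=False).pvalue)

    def test_label_permutation_invariance(self, rng):
        labels = self._labels(30)
        vals = pd.Series(rng.normal(size=60), index=labels.index)
        _c1, p1, _ = dispatch_test("f", vals, labels, "continuous")
        swapped = labels.map({1: 2, 2: 1})
        _c2, p2, _ = dispatch_test("f", vals, swapped, "continuous")
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestCompareClinical:
    def test_full_table_with_mixed_types(self, rng):
        expr, truth = make_subgrouped_expression(n_samples=80, shift_sd=2.5, seed=6)
        specs = [
            {"name": "age", "dist": "normal", "mean": 60, "sd": 8, "shift": 1.0},
            {"name": "marker", "dist": "lognormal"},
            {"name": "stage", "dist": "categorical", "levels": ["I", "II", "III"],
             "probs": [[0.4, 0.4, 0.2], [0.2, 0.3, 0.5]]},
        ]
        data = _aligned(expr, truth.subgroup_labels.to_numpy(), seed=6, specs=specs)
        labels = pd.Series(truth.subgroup_labels.to_numpy() + 1, index=expr.sample_ids)
        table = compare_clinical(labels, data.clinical, ["age", "marker", "stage"])
        assert list(table["feature"]) == ["age", "marker", "stage"]
        assert table.set_index("feature").loc["stage", "branch"] == "categorical"
        assert (table["p"] <= 1).all() and (table["p"] >= 0).all()

    def test_degenerate_feature_skipped(self, rng):
        samples = [f"s{i}" for i in range(10)]
        clin = ClinicalTable(
            pd.DataFrame({"flat": np.ones(10), "ok": rng.normal(size=10)}, index=samples),
            {"flat": "continuous", "ok": "continuous"},
        )
        labels = pd.Series([1] * 5 + [2] * 5, index=samples)
        table = compare_clinical(labels, clin, ["flat", "ok"])
        assert list(table["feature"]) == ["ok"]
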