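"""Correlational statistics: closed-form examples, independent oracles,
and invariance properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gestaltmem import (
    DegenerateDataError,
    ParameterError,
    correlation_matrix,
    make_score_table,
    mean_sd_correlation,
    mean_vs_sd_correlation,
    paired_t_test,
    partial_correlation,
    partial_from_correlations,
    pearson_test,
    spearman_corr,
    zscore_within_category,
)


class TestZScore:
    def test_simple_category(self):
        tbl = make_score_table(["a", "b", "c"], ["k"] * 3, [1.0, 2.0, 3.0],
                               [5] * 3, "distinctiveness")
        z = zscore_within_category(tbl)
        np.testing.assert_allclose(z["score"], [-1.0, 0.0, 1.0])

    def test_pooled_mean_zero_across_categories(self):
        rng = np.random.default_rng(0)
        cats = ["a"] * 30 + ["b"] * 30
        scores = np.r_[rng.normal(5, 1, 30), rng.normal(-2, 3, 30)]
        tbl = make_score_table([f"i{k}" for k in range(60)], cats, scores,
                               [5] * 60, "typicality")
        z = zscore_within_category(tbl)
        assert abs(z["score"].mean()) < 1e-12
        for _, grp in z.groupby("category"):
            assert abs(grp["score"].mean()) < 1e-12
            assert abs(grp["score"].std(ddof=1) - 1) < 1e-12

    def test_constant_category_rejected(self):
        tbl = make_score_table(["a", "b"], ["k", "k"], [1.0, 1.0], [5, 5],
                               "typicality")
        with pytest.raises(DegenerateDataError, match="k"):
            zscore_within_category(tbl)

    def test_preserves_within_category_correlations(self):
        # Per-category affine transforms cannot change within-category
        # Pearson correlations between two score tables.
        rng = np.random.default_rng(5)
        ids = [f"i{k}" for k in range(40)]
        cats = ["a"] * 20 + ["b"] * 20
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        tx = make_score_table(ids, cats, x + np.where(np.array(cats) == "a", 10, -3),
                              [5] * 40, "typicality")
        ty = make_score_table(ids, cats, y, [5] * 40, "cnn_likelihood")
        zx, zy = zscore_within_category(tx), zscore_within_category(ty)
        for cat in ("a", "b"):
            sel = np.array(cats) == cat
            r_raw = np.corrcoef(x[sel], y[sel])[0, 1]
            r_z = np.corrcoef(zx["score"][sel], zy["score"][sel])[0, 1]
            assert r_z == pytest.approx(r_raw, abs=1e-12)


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        e = pearson_test(x, 2 * x + 1)
        assert e.value == pytest.approx(1.0)
        assert e.df == 8

    def test_orthogonal_vectors_two_sided_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        e = pearson_test(x, y, direction="two_sided")
        assert e.value == pytest.approx(0.0, abs=1e-15)
        assert e.p == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=50), rng.normal(size=50)
        for direction, alt in [("two_sided", "two-sided"), ("greater", "greater"),
                               ("less", "less")]:
            mine = pearson_test(x, y, direction=direction)
            ref = stats.pearsonr(x, y, alternative=alt)
            assert mine.value == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_powered_detection_of_true_effect(self):
        # n = 617 pairs with population r = 0.5: the sample estimate stays
        # within +/-0.07 and the one-sided test is significant at .001 in
        # at least 99% of replications.
        rng = np.random.default_rng(123)
        n, reps, rho = 617, 1000, 0.5
        hits = 0
        within = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
            e = pearson_test(x, y, direction="greater")
            within += abs(e.value - rho) < 0.07
            hits += e.p < 0.001
        assert hits / reps >= 0.99
        assert within / reps >= 0.95

    def test_one_sided_relates_to_two_sided(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        two = pearson_test(x, y, direction="two_sided")
        greater = pearson_test(x, y, direction="greater")
        less = pearson_test(x, y, direction="less")
        if two.value > 0:
            assert greater.p == pytest.approx(two.p / 2, abs=1e-12)
            assert less.p == pytest.approx(1 - two.p / 2, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_test(np.ones(5), np.arange(5.0))


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.array([0.1, 2.0, 3.5, 7.0, 11.0])
        assert spearman_corr(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(6.0)
        assert spearman_corr(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 5, size=40).astype(float)
        y = rng.integers(0, 5, size=40).astype(float)
        mine = spearman_corr(x, y)
        oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert mine == pytest.approx(oracle, abs=1e-12)
        assert mine == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)


class TestPartialCorrelation:
    def test_uncorrelated_covariate_leaves_r(self):
        assert partial_from_correlations(0.3, 0.0, 0.0).value == pytest.approx(0.3)

    def test_published_values_study1_reanalysis(self):
        # Zero-order r's (-.07, -.31, .49) give a partial of ~.0988 -> .10.
        e = partial_from_correlations(-0.07, -0.31, 0.49, n=616,
                                      direction="greater")
        assert e.value == pytest.approx(0.0988, abs=0.0001)
        assert round(e.value, 2) == 0.10
        assert e.df == 613

    def test_published_values_study2_reanalysis(self):
        e = partial_from_correlations(-0.23, -0.15, 0.49, n=616,
                                      direction="less")
        assert e.value == pytest.approx(-0.1816, abs=0.0001)
        assert round(e.value, 2) == -0.18
        assert e.p < 0.001

    def test_closed_form_equals_residual_method(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            z = rng.normal(size=600)
            x = 0.4 * z + rng.normal(size=600)
            y = -0.3 * z + rng.normal(size=600)
            a = partial_correlation(x, y, z, method="closed_form")
            b = partial_correlation(x, y, z, method="residual")
            assert a.value == pytest.approx(b.value, abs=1e-10)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        z = rng.normal(size=80)
        x = 0.5 * z + rng.normal(size=80)
        y = 0.2 * z + rng.normal(size=80)
        mine = partial_correlation(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert mine.value == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert mine.p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-6)

    def test_perfect_covariate_rejected(self):
        with pytest.raises(DegenerateDataError):
            partial_from_correlations(0.5, 1.0, 0.3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        z = rng.normal(size=n)
        x = rng.uniform(-1, 1) * z + rng.normal(size=n)
        y = rng.uniform(-1, 1) * z + rng.normal(size=n)
        a = partial_correlation(x, y, z, method="closed_form")
        b = partial_correlation(x, y, z, method="residual")
        assert a.value == pytest.approx(b.value, abs=1e-10)
        assert -1.0 <= a.value <= 1.0


class TestPairedT:
    def test_identical_vectors_rejected(self):
        with pytest.raises(DegenerateDataError):
            paired_t_test(np.arange(5.0), np.arange(5.0))

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=147)
        b = a + rng.normal(0.3, 1.0, size=147)
        t, df, p = paired_t_test(a, b)
        assert df == 146

    def test_closed_form_and_scipy_agreement(self):
        rng = np.random.default_rng(6)
        a = np.array([1.0, 1.0, 1.0, 1.0]) + rng.normal(0, 1e-3, 4)
        b = np.zeros(4)
        t, df, p = paired_t_test(a, b)
        diff = a - b
        expected = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert t == pytest.approx(expected, abs=1e-10)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestCorrelationMatrix:
    def test_pair_count_and_threshold(self):
        rng = np.random.default_rng(1)
        variables = {f"v{i}": rng.normal(size=30) for i in range(5)}
        report = correlation_matrix(variables, "bonferroni", alpha=0.05)
        assert report.n_tests == 10
        flagged = [e for e in report.entries if e.bonferroni_significant]
        for e in flagged:
            assert e.p < 0.05 / 10

    def test_family_wise_error_controlled_under_null(self):
        # Independent normals: the Bonferroni-corrected family-wise error
        # over 10 tests stays near (below) alpha.
        rng = np.random.default_rng(77)
        n, k, reps, alpha = 616, 5, 1000, 0.05
        df = n - 2
        false_positives = 0
        for _ in range(reps):
            x = rng.normal(size=(k, n))
            r = np.corrcoef(x)
            iu = np.triu_indices(k, 1)
            rv = r[iu]
            tv = rv * np.sqrt(df / (1 - rv**2))
            p = 2 * stats.t.sf(np.abs(tv), df)
            false_positives += (p < alpha / len(rv)).any()
        fwe = false_positives / reps
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert fwe <= alpha + 2 * se


class TestMeanVsSD:
    def test_exact_linear_relation(self):
        means = np.array([0.2, 0.4, 0.6, 0.8])
        e = mean_sd_correlation(means, 1 - means)
        assert e.value == pytest.approx(-1.0)

    def test_df_counts_categories(self):
        e = mean_sd_correlation(np.array([0.2, 0.5, 0.6, 0.9, 0.3]),
                                np.array([0.1, 0.2, 0.15, 0.05, 0.2]))
        assert e.df == 3

    def test_binomial_ceiling_produces_negative_relation(self):
        # Per-image binomial scores with category means pushed toward 1:
        # easy categories compress their score spread.
        rng = np.random.default_rng(13)
        ids, cats, scores = [], [], []
        for c, base in enumerate(np.linspace(0.55, 0.95, 14)):
            p = np.clip(base + rng.normal(0, 0.05, 44), 0.01, 0.999)
            s = rng.binomial(74, p) / 74
            for j, v in enumerate(s):
                ids.append(f"c{c}_i{j}")
                cats.append(f"cat{c}")
                scores.append(v)
        tbl = make_score_table(ids, cats, scores, [74] * len(ids),
                               "categorizability")
        e = mean_vs_sd_correlation(tbl)
        assert e.value < 0
        assert e.df == 12
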