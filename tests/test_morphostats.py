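"""Shape-space and univariate statistics."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.decomposition import PCA as SkPCA

from morphosex.morphostats import (
    allometry_corrected_sex_effect,
    pca,
    permutation_mean_difference,
    procrustes_anova,
    summary_from_groups,
    ttest_and_effect,
    variance_explained_regression,
)


class TestPca:
    def test_single_direction_explains_everything(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=6)
        t = rng.normal(size=20)
        space = pca(np.outer(t, v))
        assert space.percent_variance[0] == pytest.approx(100.0, abs=1e-9)

    def test_percent_variances_sum_to_100(self):
        rng = np.random.default_rng(1)
        space = pca(rng.normal(size=(15, 8)))
        assert space.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_matches_sklearn_eigendecomposition(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(10, 6))
        space = pca(x)
        ref = SkPCA().fit(x)
        np.testing.assert_allclose(space.eigenvalues,
                                   ref.explained_variance_, atol=1e-10)

    def test_scores_reconstruct_centered_data(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(12, 5))
        space = pca(x)
        recon = space.scores @ space.loadings + space.mean_vector
        np.testing.assert_allclose(recon, x, atol=1e-8)
        # score covariance diagonal
        cov = np.cov(space.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            pca(np.zeros((1, 4)))


class TestVarianceExplainedRegression:
    def test_exact_linear_function_gives_100(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=30)
        v = rng.normal(size=9)
        res = variance_explained_regression(np.outer(t, v), t)
        assert res.percent_variance_explained == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_predictor_gives_0(self):
        y = np.outer(np.array([1.0, -1.0, 1.0, -1.0]), np.ones(3))
        pred = np.array([1.0, 1.0, -1.0, -1.0])
        res = variance_explained_regression(y, pred)
        assert res.percent_variance_explained == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = rng.normal(size=(12, 4))
        res = variance_explained_regression(y, x)
        design = np.column_stack([np.ones(12), x])
        beta = np.linalg.inv(design.T @ design) @ design.T @ y
        fitted = design @ beta
        ss_model = ((fitted - y.mean(0)) ** 2).sum()
        ss_total = ((y - y.mean(0)) ** 2).sum()
        assert res.percent_variance_explained == pytest.approx(
            100 * ss_model / ss_total, abs=1e-9
        )

    def test_categorical_predictor_dummy_coded(self):
        rng = np.random.default_rng(6)
        g = np.array(["a", "b", "c"] * 8)
        y = rng.normal(size=(24, 5))
        y[g == "b"] += 1.0
        res = variance_explained_regression(y, g, predictor_name="origin")
        # oracle: between-group share of total SS
        yc = y - y.mean(0)
        between = sum(
            (g == lv).sum() * ((y[g == lv].mean(0) - y.mean(0)) ** 2).sum()
            for lv in "abc"
        )
        assert res.percent_variance_explained == pytest.approx(
            100 * between / (yc ** 2).sum(), abs=1e-9
        )

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            variance_explained_regression(np.random.default_rng(0).normal(size=(8, 2)),
                                          np.ones(8))

    def test_additive_for_orthogonal_predictors(self):
        rng = np.random.default_rng(7)
        a = np.tile([1.0, -1.0], 10)
        b = np.repeat([1.0, -1.0], 10)
        y = (np.outer(a, rng.normal(size=4)) + np.outer(b, rng.normal(size=4))
             + 0.1 * rng.normal(size=(20, 4)))
        pa = variance_explained_regression(y, a).percent_variance_explained
        pb = variance_explained_regression(y, b).percent_variance_explained
        pab = variance_explained_regression(
            y, np.column_stack([a, b])
        ).percent_variance_explained
        assert pa + pb == pytest.approx(pab, abs=1e-9)


class TestAllometryCorrection:
    def test_pure_size_dependence_leaves_no_sex_effect(self):
        """Shape that depends (almost) only on size retains essentially no
        sex share of the original variance after allometric correction."""
        rng = np.random.default_rng(8)
        lncs = rng.normal(size=40)
        sex = np.tile([0.0, 1.0], 20)
        y = np.outer(lncs, rng.normal(size=6))
        y += 1e-5 * rng.normal(size=y.shape)
        res = allometry_corrected_sex_effect(y, lncs, sex)
        assert res.percent_of_total < 1e-6

    def test_recovers_orthogonal_sex_share(self):
        """Size effect plus a sex offset orthogonal to the allometric vector:
        stage 2 recovers the constructed sex share of residual variance."""
        rng = np.random.default_rng(9)
        n = 200
        lncs = rng.normal(size=n)
        sex = np.tile([0.0, 1.0], n // 2)
        v_size = np.zeros(8); v_size[0] = 1.0
        v_sex = np.zeros(8); v_sex[1] = 1.0
        noise = 0.5 * rng.normal(size=(n, 8))
        y = np.outer(lncs, v_size) + np.outer(sex - 0.5, v_sex) + noise
        res = allometry_corrected_sex_effect(y, lncs, sex)
        resid = y - np.outer(lncs, v_size)  # construction: exact residual
        expected = 100 * 0.25 / (0.25 + 0.5 ** 2 * 8)
        assert res.percent_variance_explained == pytest.approx(expected, abs=1.0)

    def test_correction_shrinks_confounded_sex_effect(self):
        """When the sex offset is parallel to allometry and the sexes differ
        in size, correcting for allometry reduces the apparent sex share."""
        rng = np.random.default_rng(10)
        n = 200
        sex = np.tile([0.0, 1.0], n // 2)
        lncs = rng.normal(size=n) * 0.3 + sex  # sexes size-separated
        v = np.zeros(6); v[0] = 1.0
        y = np.outer(lncs, v) + 0.2 * rng.normal(size=(n, 6))
        uncorrected = variance_explained_regression(y, sex).percent_variance_explained
        corrected = allometry_corrected_sex_effect(y, lncs, sex)
        assert corrected.percent_variance_explained < uncorrected
        assert corrected.percent_of_total <= corrected.percent_variance_explained

    def test_single_sex_rejected(self):
        with pytest.raises(ValueError, match="both sexes"):
            allometry_corrected_sex_effect(
                np.zeros((6, 2)), np.zeros(6), np.zeros(6)
            )


class TestPermutationMeanDifference:
    def test_exhaustive_enumeration_matches_oracle(self):
        """n = 3 vs 3: exact mode must match a full independent enumeration
        of all 20 splits."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=(6, 4))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permutation_mean_difference(x, labels, exact=True)

        def stat(mask):
            return np.linalg.norm(x[mask].mean(0) - x[~mask].mean(0))

        obs = stat(np.array([True] * 3 + [False] * 3))
        count = 0
        splits = list(combinations(range(6), 3))
        for combo in splits:
            m = np.zeros(6, bool)
            m[list(combo)] = True
            if stat(m) >= obs - 1e-12:
                count += 1
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(count / 20)

    def test_enormous_offset_gives_minimal_p(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(20, 3))
        x[:10] += 100.0
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = permutation_mean_difference(x, labels, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(16, 5))
        labels = np.array(["a", "b"] * 8)
        p1 = permutation_mean_difference(x, labels, n_perm=499, seed=42).p_value
        p2 = permutation_mean_difference(x, labels, n_perm=499, seed=42).p_value
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_three_groups_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            permutation_mean_difference(
                np.zeros((6, 2)), np.array(["a", "b", "c"] * 2)
            )

    def test_accepts_landmark_arrays(self):
        """n x k x 3 arrays are treated as flattened shape coordinates, so
        the statistic is the Procrustes distance between group means."""
        rng = np.random.default_rng(14)
        x = rng.normal(size=(10, 7, 3))
        labels = np.array(["a", "b"] * 5)
        r1 = permutation_mean_difference(x, labels, n_perm=99, seed=1)
        r2 = permutation_mean_difference(x.reshape(10, -1), labels, n_perm=99, seed=1)
        assert r1.observed_statistic == pytest.approx(r2.observed_statistic)
        assert r1.p_value == r2.p_value


class TestProcrustesAnova:
    def test_single_factor_equals_regression(self):
        rng = np.random.default_rng(15)
        sex = np.array(["F", "M"] * 12)
        y = rng.normal(size=(24, 5))
        y[sex == "M"] += 0.5
        tab = procrustes_anova(y, {"sex": sex}, n_perm=0)
        reg = variance_explained_regression(y, sex)
        assert tab.percent[0] == pytest.approx(reg.percent_variance_explained,
                                               abs=1e-9)

    def test_null_second_factor_is_diffuse(self):
        rng = np.random.default_rng(16)
        f1 = np.array(["x", "y"] * 20)
        noise_factor = rng.permutation(np.array(["u", "v"] * 20))
        y = rng.normal(size=(40, 6))
        y[f1 == "y"] += 1.0
        tab = procrustes_anova(y, {"f1": f1, "null": noise_factor},
                               n_perm=199, seed=3)
        assert tab.percent[1] < 5.0
        assert tab.p_values[1] > 0.05  # diffuse, not significant

    def test_sequential_ss_partition_total(self):
        rng = np.random.default_rng(17)
        f1 = np.array(["x", "y"] * 15)
        f2 = np.repeat(["u", "v", "w"], 10)
        y = rng.normal(size=(30, 4))
        tab = procrustes_anova(y, {"f1": f1, "f2": f2}, n_perm=0)
        yc = y - y.mean(0)
        assert tab.ss.sum() + tab.ss_residual == pytest.approx(
            (yc ** 2).sum(), abs=1e-9
        )
        assert list(tab.df) == [1, 2]

    def test_rank_deficient_design_names_term(self):
        f1 = np.array(["x", "y"] * 10)
        with pytest.raises(ValueError, match="aliased"):
            procrustes_anova(
                np.random.default_rng(0).normal(size=(20, 3)),
                {"f1": f1, "dup": f1.copy()}, n_perm=0,
            )


class TestUnivariateStats:
    def test_equal_group_means(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        sex = np.array(["F"] * 3 + ["M"] * 3)
        st = ttest_and_effect(vals, sex)
        assert st.average_difference == pytest.approx(0.0)
        assert st.cohens_d_total == pytest.approx(0.0)
        assert st.p_value == pytest.approx(1.0)

    def test_small_sample_matches_hand_computation(self):
        """6 explicit values: t and p checked against the textbook pooled
        formula evaluated by hand."""
        f = np.array([10.0, 12.0, 11.0])
        m = np.array([14.0, 15.0, 16.0])
        st = ttest_and_effect(np.r_[f, m], np.array(["F"] * 3 + ["M"] * 3))
        sp2 = (2 * f.var(ddof=1) + 2 * m.var(ddof=1)) / 4
        t_hand = (f.mean() - m.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=4)
        assert st.t_statistic == pytest.approx(t_hand, abs=1e-12)
        assert st.p_value == pytest.approx(p_hand, abs=1e-12)

    def test_raw_agrees_with_summary_mode(self):
        rng = np.random.default_rng(18)
        vals = np.r_[rng.normal(10, 2, 14), rng.normal(12, 2.5, 17)]
        sex = np.array(["F"] * 14 + ["M"] * 17)
        st = ttest_and_effect(vals, sex)
        sm = summary_from_groups(
            14, vals[:14].mean(), vals[:14].std(ddof=1),
            17, vals[14:].mean(), vals[14:].std(ddof=1),
        )
        assert st.t_statistic == pytest.approx(sm.t_statistic, abs=1e-12)
        assert st.cohens_d_total == pytest.approx(sm.cohens_d_total, abs=1e-12)
        assert st.cohens_d_pooled == pytest.approx(sm.cohens_d_pooled, abs=1e-12)

    def test_published_corpus_width_effect_size(self):
        """European corpus width summaries (44.1 +/- 3.5 mm, n=31 vs
        52.4 +/- 4.3 mm, n=27) give a total-sample-SD Cohen's D of 1.46."""
        st = summary_from_groups(31, 44.1, 3.5, 27, 52.4, 4.3)
        assert round(st.cohens_d_total, 2) == 1.46

    def test_published_corpus_depth_effect_size(self):
        """Complete-sample corpus depth (28.3 +/- 2.9, n=68 vs 31.8 +/- 2.8,
        n=77) gives a total-sample-SD Cohen's D of 1.05."""
        st = summary_from_groups(68, 28.3, 2.9, 77, 31.8, 2.8)
        assert round(st.cohens_d_total, 2) == 1.05

    def test_identical_groups_zero_effect(self):
        st = summary_from_groups(10, 5.0, 1.0, 12, 5.0, 1.0)
        assert st.average_difference == 0.0
        assert st.cohens_d_total == 0.0

    def test_zero_within_sd_total_is_between_sd(self):
        st = summary_from_groups(4, 1.0, 0.0, 4, 3.0, 0.0)
        grand = 2.0
        between_sd = np.sqrt((4 * 1 + 4 * 1) / 8)  # (mean - grand)^2 = 1
        assert st.cohens_d_total == pytest.approx(2.0 / between_sd, abs=1e-12)

    def test_single_sex_rejected(self):
        with pytest.raises(ValueError):
            ttest_and_effect(np.arange(5.0), np.array(["F"] * 5))
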