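"""Covariate-adjusted contrasts, permutation p-values, BH-FDR, stratification."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conngrad import ancova_t, bh_fdr, encode_covariates, permutation_test, stratify
from conngrad.stats import PermutationGroupContrast, _design_matrix

from conftest import small_config
from conngrad import simulate_cohort, contrast_pipeline


class TestAncovaT:
    def test_constant_feature_degenerate_t_zero(self):
        t = ancova_t([1.0] * 8, ["patient"] * 4 + ["control"] * 4,
                     age=np.arange(8), sex=["M", "F"] * 4)
        assert t == 0.0

    def test_matches_statsmodels_ols(self, rng):
        """Independent oracle: the group term's t from a statsmodels OLS fit."""
        for _ in range(5):
            n = 16
            group = np.array(["patient"] * 8 + ["control"] * 8)
            age = rng.uniform(20, 60, n)
            sex = rng.choice(["M", "F"], n)
            y = rng.standard_normal(n) + 0.8 * (group == "patient")
            x = sm.add_constant(
                np.column_stack([(group == "patient").astype(float), age, (sex == "F").astype(float)])
            )
            expected = sm.OLS(y, x).fit().tvalues[1]
            assert ancova_t(y, group, age=age, sex=sex) == pytest.approx(expected, abs=1e-8)

    def test_covariate_free_equals_pooled_two_sample_t(self, rng):
        y = rng.standard_normal(20)
        group = np.array(["patient"] * 10 + ["control"] * 10)
        expected = sps.ttest_ind(y[:10], y[10:], equal_var=True).statistic
        assert ancova_t(y, group) == pytest.approx(expected, abs=1e-10)

    def test_orthogonal_covariates_near_two_sample_t(self, rng):
        """With covariates orthogonal to group, adjustment changes t negligibly."""
        n = 40
        group = np.array(["patient"] * 20 + ["control"] * 20)
        g = (group == "patient").astype(float)
        deltas = []
        for _ in range(100):
            age = rng.uniform(20, 60, n)
            age[g == 1] -= age[g == 1].mean()  # exactly orthogonal to group
            age[g == 0] -= age[g == 0].mean()
            y = rng.standard_normal(n) + 0.5 * g
            t_cov = ancova_t(y, group, age=age)
            t_plain = ancova_t(y, group)
            deltas.append(abs(t_cov - t_plain))
        assert np.mean(deltas) < 0.05

    def test_rank_deficiency_raises(self):
        with pytest.raises(ValueError, match="rank deficient"):
            ancova_t([1, 2, 3, 4, 5, 6], ["patient"] * 3 + ["control"] * 3, sex=["F"] * 6)


class TestPermutationTest:
    def test_exhaustive_enumeration_on_toy(self):
        """p equals the hand count over explicitly enumerated relabelings."""
        y = np.array([3.0, 2.9, 1.0, 1.1])
        group = np.array(["patient", "patient", "control", "control"])
        perms = np.array([[0, 2, 1, 3], [3, 1, 2, 0], [2, 3, 0, 1]])
        res = permutation_test(y[:, None], group, n_perm=3, seed=0, permutations=perms)
        g = np.array([1.0, 1.0, 0.0, 0.0])
        t_obs = sps.ttest_ind(y[g == 1], y[g == 0], equal_var=True).statistic
        count = 0
        for p in perms:
            gp = g[p]
            t_p = sps.ttest_ind(y[gp == 1], y[gp == 0], equal_var=True).statistic
            count += abs(t_p) > abs(t_obs)
        assert res.p_perm[0] == pytest.approx(count / 3)

    def test_all_smaller_permutations_give_p_exactly_zero(self, rng):
        """Strictly-greater counting admits p = 0 when no permuted |t| exceeds."""
        y = np.concatenate([rng.normal(10, 0.1, 10), rng.normal(-10, 0.1, 10)])
        group = np.array(["patient"] * 10 + ["control"] * 10)
        res = permutation_test(y[:, None], group, n_perm=200, seed=1)
        assert res.p_perm[0] == 0.0

    def test_identical_seed_reproducible(self, rng):
        feats = rng.standard_normal((20, 15))
        group = np.array(["patient"] * 10 + ["control"] * 10)
        a = permutation_test(feats, group, n_perm=100, seed=7)
        b = permutation_test(feats, group, n_perm=100, seed=7)
        np.testing.assert_array_equal(a.p_perm, b.p_perm)

    def test_null_feature_calibration(self, rng):
        """Independent features: rejection fraction near nominal 5%."""
        feats = rng.standard_normal((30, 200))
        group = np.array(["patient"] * 15 + ["control"] * 15)
        res = permutation_test(feats, group, n_perm=500, seed=3)
        rate = (res.p_perm < 0.05).sum()
        lo, hi = sps.binom.interval(0.99, 200, 0.05)
        assert lo <= rate <= hi

    def test_add_one_correction_bounds_p_away_from_zero(self, rng):
        y = np.concatenate([rng.normal(5, 0.1, 8), rng.normal(-5, 0.1, 8)])
        group = np.array(["patient"] * 8 + ["control"] * 8)
        est = PermutationGroupContrast(n_permutations=99, random_state=0, add_one_correction=True)
        est.fit(y[:, None], group)
        assert est.p_[0] == pytest.approx(1 / 100)

    def test_direction_labels(self, rng):
        feats = np.column_stack([
            np.r_[np.ones(10), np.zeros(10)],
            np.r_[np.zeros(10), np.ones(10)],
        ]) + rng.standard_normal((20, 2)) * 0.01
        group = np.array(["patient"] * 10 + ["control"] * 10)
        res = permutation_test(feats, group, n_perm=10, seed=0)
        assert res.direction[0] == "expansion" and res.direction[1] == "contraction"


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.123]), [0.123])

    def test_matches_step_up_formula(self, rng):
        """Oracle: direct q_(i) = min_{j>=i} m p_(j) / j."""
        p = rng.random(30)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            bh_fdr([0.1, np.nan])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_step_up_properties(self, p):
        """q in [0, 1], q >= p element-wise, and order of p preserved in q."""
        p = np.array(p)
        q = bh_fdr(p)
        assert ((q >= 0) & (q <= 1)).all()
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestStratify:
    def test_constant_t_gives_constant_class_means(self, planted_cohort, planted_pipeline):
        res = planted_pipeline.result
        res_const = type(res)(
            region_ids=res.region_ids, t_obs=np.ones_like(res.t_obs), p_perm=res.p_perm,
            q_fdr=res.q_fdr, significant=res.significant, direction=res.direction,
            n_permutations=res.n_permutations,
        )
        summary = stratify(res_const, planted_cohort.atlas, "network7")
        for v in summary.class_means.values():
            assert v == pytest.approx(1.0)

    def test_weighted_class_means_recover_grand_mean(self, planted_cohort, planted_pipeline):
        res = planted_pipeline.result
        labels = planted_cohort.atlas.network_labels()
        summary = stratify(res, planted_cohort.atlas, "network7")
        sizes = labels.value_counts()
        weighted = sum(summary.class_means[c] * sizes[c] for c in summary.class_means) / sizes.sum()
        assert weighted == pytest.approx(res.t_obs.mean())

    def test_hierarchy_partition(self, planted_cohort, planted_pipeline):
        summary = stratify(planted_pipeline.result, planted_cohort.atlas, "hierarchy4")
        assert set(summary.class_means) == {"idiotypic", "unimodal", "heteromodal", "paralimbic"}

    def test_planted_limbic_has_maximum_mean_t(self, planted_cohort, planted_pipeline):
        assert planted_pipeline.network_summary.max_class() == "limbic"
        assert planted_pipeline.hierarchy_summary.max_class() == "paralimbic"


def test_design_matrix_structure():
    x = _design_matrix(np.array([1.0, 0.0, 1.0, 0.0]), np.array([[30.0, 1], [45, 1], [50, 0], [62, 0]]))
    assert x.shape == (4, 4)
    np.testing.assert_array_equal(x[:, 0], 1.0)


def test_encode_covariates_sex_indicator():
    cov = encode_covariates(age=[30, 40], sex=["F", "M"])
    np.testing.assert_array_equal(cov, [[30.0, 1.0], [40.0, 0.0]])
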