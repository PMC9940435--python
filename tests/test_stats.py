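"""Covariate adjustment, group tests, FDR and partial correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from msdyn.stats import (chi_square_2x2, fdr_bh, midas_category,
                         partial_pearson, permutation_pvalues,
                         permutation_test, residualize, subgroup_split,
                         two_sample_t, welch_t_from_summary)


class TestResidualize:
    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 6.0])
        assert np.allclose(residualize(y, None), y - 3.0)

    def test_perfect_fit_leaves_nothing(self):
        age = np.arange(20.0, 40.0)
        y = 3.0 * age + 7.0
        assert np.max(np.abs(residualize(y, age))) < 1e-9

    def test_orthogonal_to_design(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        C = rng.standard_normal((30, 3))
        r = residualize(y, C)
        assert np.max(np.abs(C.T @ r)) < 1e-10
        assert abs(r.sum()) < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(25)
        C = rng.standard_normal((25, 2))
        once = residualize(y, C)
        assert np.allclose(residualize(once, C), once)

    def test_collinear_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        age = rng.standard_normal(20)
        C = np.column_stack([age, 2 * age])
        with pytest.warns(UserWarning, match="rank-deficient"):
            r = residualize(rng.standard_normal(20), C)
        assert np.isfinite(r).all()


class TestTwoSampleT:
    def test_hand_computed_effect_size(self):
        t, p, d = two_sample_t([1, 2, 3], [4, 5, 6])
        assert d == pytest.approx(-3.0)
        assert t < 0

    def test_identical_groups_null(self):
        t, p, d = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 12))
        t, p, _ = two_sample_t(x, y)
        # independent recomputation from the pooled-variance formula
        sp2 = (11 * x.var(ddof=1) + 11 * y.var(ddof=1)) / 22
        t_exp = (x.mean() - y.mean()) / np.sqrt(sp2 * (2 / 12))
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_exp), 22), abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            t, p, d = two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(t)


class TestSummaryStatistics:
    @pytest.mark.parametrize("m1,s1,m2,s2,printed", [
        (34.88, 1.95, 37.92, 2.54, 0.94),     # age
        (13.96, 0.51, 13.77, 0.58, 0.24),     # education
    ])
    def test_welch_t_reproduces_printed_demographics(self, m1, s1, m2, s2, printed):
        assert abs(welch_t_from_summary(m1, s1, m2, s2)) == pytest.approx(
            printed, abs=0.01)

    def test_equal_means_give_zero(self):
        assert welch_t_from_summary(5.0, 1.0, 5.0, 2.0) == 0.0

    def test_nonpositive_sem_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1.0, 0.0, 2.0, 1.0)

    def test_chi_square_reproduces_printed_sex_table(self):
        chi2, p = chi_square_2x2(3, 21, 5, 21)
        assert chi2 == pytest.approx(0.42, abs=0.01)

    def test_proportional_table_is_independent(self):
        chi2, _ = chi_square_2x2(10, 10, 10, 10)
        assert chi2 == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_chi_square_matches_expected_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 40, size=4)
        chi2, _ = chi_square_2x2(a, b, c, d)
        obs = np.array([[a, b], [c, d]], float)
        n = obs.sum()
        exp = np.outer(obs.sum(1), obs.sum(0)) / n
        assert chi2 == pytest.approx(np.sum((obs - exp) ** 2 / exp), abs=1e-10)


class TestPermutation:
    def test_identical_multisets_near_one(self):
        v = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        assert permutation_test(v, labels, n_iter=500, seed=0) > 0.5

    def test_separated_groups_minimal_p(self):
        v = np.concatenate([np.zeros(10), np.ones(10) * 10])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        p = permutation_test(v, labels, n_iter=10000, seed=0)
        assert p <= 0.001

    def test_agrees_with_parametric_on_gaussian_data(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(15) + 0.8
        y = rng.standard_normal(15)
        v = np.concatenate([x, y])
        labels = np.array(["a"] * 15 + ["b"] * 15)
        _, p_param, _ = two_sample_t(x, y)
        p_perm = permutation_test(v, labels, n_iter=10000, seed=1)
        assert abs(p_perm - p_param) < 0.02

    def test_matrix_version_agrees_with_scalar(self):
        rng = np.random.default_rng(5)
        V = rng.standard_normal((30, 3))
        V[:12] += np.array([1.0, 0.0, 0.3])
        labels = np.array(["a"] * 12 + ["b"] * 18)
        pm = permutation_pvalues(V, labels, n_iter=4000, seed=2)
        for j in range(3):
            ps = permutation_test(V[:, j], labels, n_iter=4000, seed=3)
            assert abs(pm[j] - ps) < 0.03


class TestFDR:
    def test_step_up_rejects_all_when_dense(self):
        rejected, adjusted = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert rejected.all()

    def test_single_p_reduces_to_raw_threshold(self):
        rejected, _ = fdr_bh(np.array([0.04]))
        assert rejected.all()
        rejected, _ = fdr_bh(np.array([0.06]))
        assert not rejected.any()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_never_rejects_above_alpha(self, pvals):
        pvals = np.array(pvals)
        rejected, adjusted = fdr_bh(pvals, alpha=0.05)
        assert not np.any(rejected & (pvals > 0.05))
        order = np.argsort(pvals)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_nan_passes_through(self):
        rejected, adjusted = fdr_bh(np.array([0.01, np.nan]))
        assert rejected[0] and not rejected[1]
        assert np.isnan(adjusted[1])


class TestPartialPearson:
    def test_identity_pair(self):
        x = np.random.default_rng(6).standard_normal(20)
        res = partial_pearson(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.ci95[1] == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0)

    def test_conditional_independence_removed(self):
        rng = np.random.default_rng(7)
        age = rng.standard_normal(200)
        x = age
        y = age + 0.1 * rng.standard_normal(200)
        raw = np.corrcoef(x, y)[0, 1]
        res = partial_pearson(x, y, age)
        assert raw > 0.9
        assert abs(res.r) < 0.2

    def test_ci_ordering_and_df(self):
        rng = np.random.default_rng(8)
        x, y = rng.standard_normal((2, 24))
        cov = rng.standard_normal((24, 2))
        res = partial_pearson(x, y, cov)
        assert res.ci95[0] <= res.r <= res.ci95[1]
        assert res.n == 24

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            partial_pearson(np.ones(5), np.ones(5), np.ones((5, 2)))


class TestMidas:
    @pytest.mark.parametrize("score,expected", [
        (0, "little_or_none"), (5, "little_or_none"),
        (6, "mild"), (7, "mild"), (10, "mild"),
        (11, "moderate"), (20, "moderate"),
        (21, "severe"), (80, "severe"),
    ])
    def test_grade_bins(self, score, expected):
        assert midas_category(score) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            midas_category(-1)

    def test_fractional_rejected(self):
        with pytest.raises(ValueError):
            midas_category(5.5)


class TestSubgroups:
    def _patients(self):
        return pd.DataFrame({
            "subject_id": list("abcdef"),
            "duration_years": [4, 6, 2, 8, 5, 9],
            "attacks_per_month": [2, 3, 1, 5, 2, 4],
            "pain_side": ["left", "left", "right", "bilateral", "left", "right"],
            "medication": ["ibuprofen", "paracetamol", "ibuprofen",
                           "ibuprofen", "paracetamol", "paracetamol"],
        })

    def test_duration_threshold_strict(self):
        g1, g2 = subgroup_split(self._patients(), "duration")
        assert set(g1["duration_years"]) == {6, 8, 9}
        assert 5 in set(g2["duration_years"])

    def test_attacks_boundary_value(self):
        g1, g2 = subgroup_split(self._patients(), "attacks")
        assert 2 not in set(g1["attacks_per_month"])   # >2 group
        assert 2 in set(g2["attacks_per_month"])

    def test_pain_side_split(self):
        g1, g2 = subgroup_split(self._patients(), "pain_side")
        assert set(g1["pain_side"]) == {"left"}

    def test_degenerate_partition_warns(self):
        t = self._patients()
        t["pain_side"] = "left"
        with pytest.warns(UserWarning, match="fewer than 3"):
            g1, g2 = subgroup_split(t, "pain_side")
        assert len(g2) == 0

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            subgroup_split(self._patients(), "phase_of_moon")
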