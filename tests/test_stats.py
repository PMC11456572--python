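import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psmdnet.stats import (
    chi_square_2x2,
    compare_groups,
    delong_compare,
    fdr_bh,
    hierarchical_regression,
    mann_whitney_z,
    partial_correlation,
    roc_auc,
)

from _oracles import brute_fdr_bh, partial_corr_1cov, rank_sum_auc


class TestCompareGroups:
    def test_identical_groups(self):
        v = np.concatenate([np.arange(1, 11), np.arange(1, 11)])
        g = np.array(["a"] * 10 + ["b"] * 10)
        res = compare_groups(v.astype(float), g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_pooled_t_hand_computed(self):
        # means 2 vs 4, pooled variance 2.5, se = 1 -> t = -2, df = 8
        a = np.array([0.0, 1, 2, 3, 4])
        b = np.array([2.0, 3, 4, 5, 6])
        res = compare_groups(
            np.concatenate([a, b]), np.array(["a"] * 5 + ["b"] * 5)
        )
        assert res.test == "pooled_t"
        assert res.statistic == pytest.approx(-2.0)

    def test_mann_whitney_perfect_separation(self):
        a = np.arange(10.0)
        b = np.arange(100.0, 110.0)
        u, z, p = mann_whitney_z(a, b)
        assert u == 0.0
        assert p < 0.001

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            compare_groups(
                np.array([1.0, 2, 3, 4]), np.array(["a", "a", "b", "b"])
            )

    def test_nonnormal_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        a = np.exp(rng.normal(0, 2.5, 80))  # heavily skewed
        b = np.exp(rng.normal(0, 2.5, 80))
        res = compare_groups(
            np.concatenate([a, b]), np.array(["a"] * 80 + ["b"] * 80)
        )
        assert res.test == "mann_whitney"
        assert "(" in res.summary_a  # median (Q1, Q3) formatting


class TestChiSquare:
    def test_balanced(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0
        assert p == 1.0

    def test_hand_formula(self):
        # (ad - bc)^2 n / (r1 r2 c1 c2) = 300^2 * 60 / 30^4
        chi2, _ = chi_square_2x2([[20, 10], [10, 20]])
        assert chi2 == pytest.approx(20.0 / 3.0)

    def test_near_balanced_sex_ratio(self):
        chi2, p = chi_square_2x2([[23, 33], [26, 38]])
        assert chi2 < 0.01
        assert p > 0.9

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_auc(np.array([1.0, 2, 10, 11]), np.array([0, 0, 1, 1]))
        assert res.auc == 1.0

    def test_three_of_four_pairs(self):
        res = roc_auc(np.array([1.0, 2, 3, 4]), np.array([0, 1, 0, 1]))
        assert res.auc == pytest.approx(0.75)

    def test_all_ties(self):
        res = roc_auc(np.ones(10), np.array([0, 1] * 5))
        assert res.auc == 0.5

    def test_rank_sum_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            res = roc_auc(scores, labels)
            expected = rank_sum_auc(scores, labels)
            if expected < 0.5:
                expected = 1.0 - expected
            assert res.auc == pytest.approx(expected, abs=1e-12)

    def test_orientation_flag(self):
        res = roc_auc(np.array([4.0, 3, 2, 1]), np.array([0, 0, 1, 1]))
        assert res.flipped
        assert res.auc == 1.0

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.ones(4))


class TestDeLong:
    def test_identical_scores_degenerate(self):
        s = np.arange(10.0)
        labels = np.array([0, 1] * 5)
        with pytest.raises(ValueError, match="degenerate"):
            delong_compare(s, s.copy(), labels)

    def test_monotone_transform_p_one(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        p = delong_compare(s, np.exp(s), labels)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_power_against_noise(self):
        """Informative scores (AUC ~ 0.8) vs pure noise at n=200/200."""
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(100):
            labels = np.repeat([0, 1], 200)
            informative = rng.normal(size=400) + 1.2 * labels
            noise = rng.normal(size=400)
            if delong_compare(informative, noise, labels) < 0.05:
                rejections += 1
        assert rejections >= 90


class TestPartialCorrelation:
    def test_no_covariates_is_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = partial_correlation(x, y)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_closed_form_construction(self):
        """Exact sample correlations r_xy = r_xz = r_yz = 0.5 give
        partial r = (0.5 - 0.25) / 0.75 = 1/3."""
        n = 12
        # centered orthonormal basis vectors
        e = np.linalg.qr(np.random.default_rng(3).normal(size=(n, 4)))[0]
        e = e - e.mean(axis=0)
        e, _ = np.linalg.qr(e)
        z = e[:, 0]
        x = 0.5 * e[:, 0] + np.sqrt(0.75) * e[:, 1]
        y = 0.5 * e[:, 0] + 0.25 / np.sqrt(0.75) * e[:, 1] + np.sqrt(
            1 - 0.25 - 0.0625 / 0.75
        ) * e[:, 2]
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(0.5, abs=1e-10)
        res = partial_correlation(x, y, z[:, None])
        assert res.r == pytest.approx(1.0 / 3.0, abs=1e-9)
        assert res.r == pytest.approx(partial_corr_1cov(x, y, z), abs=1e-12)

    def test_matches_recursive_formula_randomly(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=25)
            z = rng.normal(size=25)
            y = 0.5 * z + rng.normal(size=25)
            res = partial_correlation(x, y, z[:, None])
            assert res.r == pytest.approx(partial_corr_1cov(x, y, z), abs=1e-12)

    def test_covariate_equal_to_variable_errors(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=20)
        x = rng.normal(size=20)
        with pytest.raises(ValueError):
            partial_correlation(x, z, z[:, None])


class TestHierarchicalRegression:
    def test_orthogonal_predictors_unit_vif(self):
        n = 40
        e = np.linalg.qr(np.random.default_rng(5).normal(size=(n, 3)))[0]
        e = e - e.mean(axis=0)
        e, _ = np.linalg.qr(e)
        b1 = pd.DataFrame({"c1": e[:, 0]})
        b2 = pd.DataFrame({"m1": e[:, 1], "m2": e[:, 2]})
        y = e[:, 1] + np.random.default_rng(6).normal(0, 0.1, n)
        res = hierarchical_regression(y, b1, b2)
        for v in res.vif.values():
            assert v == pytest.approx(1.0, abs=1e-6)

    def test_perfect_fit(self):
        x = np.linspace(0, 1, 20)
        res = hierarchical_regression(
            2.0 * x, pd.DataFrame(index=range(20)), pd.DataFrame({"x": x})
        )
        assert res.betas["x"] == pytest.approx(1.0)
        assert res.r2_adj == pytest.approx(1.0)

    def test_singular_design_names_column(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        b1 = pd.DataFrame({"a": x})
        b2 = pd.DataFrame({"b": 2.0 * x, "c": rng.normal(size=30)})
        with pytest.raises(ValueError, match="collinear"):
            hierarchical_regression(rng.normal(size=30), b1, b2)

    def test_r2_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        n = 25
        X = rng.normal(size=(n, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(size=n)
        res = hierarchical_regression(
            y,
            pd.DataFrame({"c": X[:, 0]}),
            pd.DataFrame({"m1": X[:, 1], "m2": X[:, 2]}),
        )
        # brute force via normal equations
        D = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        sse = ((y - D @ beta) ** 2).sum()
        sst = ((y - y.mean()) ** 2).sum()
        assert res.r2_full == pytest.approx(1.0 - sse / sst, rel=1e-10)


class TestFdrBH:
    def test_single_p_unchanged(self):
        assert fdr_bh([0.03])[0] == pytest.approx(0.03)

    def test_stepup_arithmetic(self):
        adj = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_hand_recipe(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 30)))
            assert np.allclose(fdr_bh(p), brute_fdr_bh(p), atol=1e-12)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_raw_p(self, ps):
        p = np.asarray(ps)
        adj = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)
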