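"""Chi-square tests, Sidak thresholds, and the snowball AIC comparison."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dmimap.regions import SnowballDataset
from dmimap.stats import (
    chisq_gof,
    chisq_homogeneity,
    fit_poly_gaussian,
    sidak_threshold,
    snowball_compare,
    uniform_expected,
)

SCREEN_POINTS = SnowballDataset(((0.03, 0), (0.03, 0), (0.11, 2), (0.11, 2), (0.24, 12)))


class TestChisqGof:
    def test_stage_distribution_of_lethals(self):
        # 9 embryonic, 0 larval, 3 pupal lethals against a uniform spread
        res = chisq_gof([9, 0, 3], uniform_expected(12, 3))
        assert res.statistic == pytest.approx(10.5, abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(math.exp(-5.25), rel=1e-12)

    def test_perfect_fit(self):
        res = chisq_gof([4, 4, 4], [4, 4, 4])
        assert res.statistic == 0.0 and res.p == 1.0

    @pytest.mark.parametrize(
        "obs, exp",
        [([1, 2], [1, 0]), ([1, 2], [1, -1]), ([1, 2, 3], [1, 2]), ([5], [5])],
    )
    def test_invalid_inputs_rejected(self, obs, exp):
        with pytest.raises(ValueError):
            chisq_gof(obs, exp)

    @given(st.floats(0.0, 50.0))
    def test_df2_upper_tail_is_closed_form(self, x):
        """At df = 2 the chi-square upper tail is exactly exp(-x/2)."""
        from dmimap.stats import _chisq_p

        assert _chisq_p(x, 2) == pytest.approx(math.exp(-x / 2), rel=1e-12)

    @given(
        st.lists(st.integers(0, 50), min_size=3, max_size=6),
        st.lists(st.integers(1, 50), min_size=3, max_size=6),
    )
    def test_agrees_with_scipy(self, obs, exp):
        k = min(len(obs), len(exp))
        obs, exp = obs[:k], [float(e) for e in exp[:k]]
        exp = [e * sum(obs) / sum(exp) for e in exp]  # match totals
        if sum(obs) == 0:
            return
        ours = chisq_gof(obs, exp)
        ref = scipy.stats.chisquare(obs, exp)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-300)


class TestChisqHomogeneity:
    def test_identical_row_proportions_give_zero(self):
        res = chisq_homogeneity([[10, 30, 60], [5, 15, 30]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 2

    @given(
        st.integers(1, 40), st.integers(1, 40), st.integers(1, 40),
        st.integers(1, 40),
    )
    def test_2x2_matches_textbook_closed_form(self, a, b, c, d):
        n = a + b + c + d
        closed = (
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        res = chisq_homogeneity([[a, b], [c, d]])
        assert res.df == 1
        assert res.statistic == pytest.approx(closed, rel=1e-9)

    def test_p_decreases_as_association_grows_at_fixed_margins(self):
        ps = [
            chisq_homogeneity([[25 + k, 25 - k], [25 - k, 25 + k]]).p
            for k in range(0, 20, 4)
        ]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chisq_homogeneity([[0, 0], [3, 4]])


class TestSidak:
    def test_published_thresholds(self):
        # 18 cuticle-defect comparisons and 6 viability/longevity models
        assert sidak_threshold(0.05, 18) == pytest.approx(2.8e-3, rel=5e-2)
        assert sidak_threshold(0.05, 6) == pytest.approx(8.512e-3, rel=5e-4)

    def test_identity_at_single_comparison(self):
        assert sidak_threshold(0.05, 1) == pytest.approx(0.05, rel=1e-12)

    @given(st.floats(1e-6, 0.5), st.integers(1, 1000))
    def test_inverse_identity_and_monotone_in_m(self, alpha, m):
        t = sidak_threshold(alpha, m)
        assert 1 - (1 - t) ** m == pytest.approx(alpha, rel=1e-9)
        if m > 1:
            assert t < sidak_threshold(alpha, m - 1)

    @pytest.mark.parametrize("alpha, m", [(0.0, 5), (1.0, 5), (0.05, 0)])
    def test_domain_errors(self, alpha, m):
        with pytest.raises(ValueError):
            sidak_threshold(alpha, m)


class TestFitPolyGaussian:
    def test_collinear_points_flagged_degenerate(self):
        data = SnowballDataset(((0.0, 1.0), (1.0, 3.0), (2.0, 5.0)))
        fit = fit_poly_gaussian(data, 1)
        assert fit.degenerate and fit.aic == -math.inf

    def test_coefficient_recovery_on_noisy_line(self):
        rng = np.random.default_rng(12345)
        x = np.linspace(0, 1, 60)
        y = 1.5 + 4.0 * x + rng.normal(0, 0.3, x.size)
        fit = fit_poly_gaussian(SnowballDataset(tuple(zip(x, y))), 1)
        # standard errors of OLS slope/intercept at sigma=0.3, n=60
        X = np.vander(x, 2, increasing=True)
        cov = 0.3**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        assert abs(fit.coefficients[0] - 1.5) < 3 * se[0]
        assert abs(fit.coefficients[1] - 4.0) < 3 * se[1]

    def test_refit_is_deterministic(self):
        f1 = fit_poly_gaussian(SCREEN_POINTS, 1)
        f2 = fit_poly_gaussian(SCREEN_POINTS, 1)
        assert f1 == f2

    def test_aic_matches_direct_gaussian_mle(self):
        fit = fit_poly_gaussian(SCREEN_POINTS, 1)
        n = fit.n
        sigma2 = fit.rss / n
        x = np.array(SCREEN_POINTS.xs)
        y = np.array(SCREEN_POINTS.ys)
        pred = fit.coefficients[0] + fit.coefficients[1] * x
        loglik = np.sum(scipy.stats.norm.logpdf(y, pred, math.sqrt(sigma2)))
        assert fit.loglik == pytest.approx(loglik, rel=1e-9)
        assert fit.aic == pytest.approx(2 * 3 - 2 * loglik, rel=1e-9)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1, 40)
        y = rng.uniform(0, 5, 40)
        fit = fit_poly_gaussian(SnowballDataset(tuple(zip(x, y))), 2)
        design = np.vander(x, 3, increasing=True)
        resid = y - design @ np.array(fit.coefficients)
        assert np.abs(design.T @ resid).max() < 1e-8

    def test_too_few_points_rejected(self):
        three = SnowballDataset(((0.0, 0.0), (1.0, 2.0), (2.0, 12.0)))
        with pytest.raises(ValueError, match="need more than"):
            fit_poly_gaussian(three, 2)

    def test_collinear_design_rejected_by_name(self):
        same_x = SnowballDataset(((0.1, 0), (0.1, 1), (0.1, 2), (0.1, 3), (0.2, 4)))
        with pytest.raises(ValueError, match="collinear"):
            fit_poly_gaussian(same_x, 2)

    def test_pure_power_form_fits_through_origin(self):
        x = np.array([0.5, 1.0, 2.0, 3.0])
        data = SnowballDataset(tuple(zip(x, 3.0 * x**2)))
        fit = fit_poly_gaussian(data, 2, form="pure")
        assert fit.degenerate
        assert fit.coefficients[0] == pytest.approx(3.0, rel=1e-9)


class TestSnowballCompare:
    def test_screen_dataset_prefers_quadratic(self):
        cmp_ = snowball_compare(SCREEN_POINTS)
        assert cmp_.preferred_degree == 2
        assert cmp_.quadratic.degenerate  # exact interpolation of 3 abscissae
        assert cmp_.linear.rss > 0
        assert not cmp_.linear.degenerate

    def test_linear_data_prefers_linear_model_at_the_aic_overfit_rate(self):
        # AIC admits a superfluous quadratic term when Δ(2·loglik) > 2, an
        # event of asymptotic probability P(χ²₁ > 2) ≈ 0.157; the linear model
        # should therefore win ≈ 84% of replicates, and always a majority
        wins = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            x = np.linspace(0, 1, 50)
            y = 2.0 + 5.0 * x + rng.normal(0, 1.0, x.size)
            cmp_ = snowball_compare(SnowballDataset(tuple(zip(x, y))))
            wins += cmp_.preferred_degree == 1
        expected = scipy.stats.chi2.cdf(2, df=1)  # ≈ 0.843
        assert abs(wins / n_runs - expected) < 0.12

    def test_quadratic_data_prefers_quadratic_model(self):
        rng = np.random.default_rng(99)
        x = np.linspace(0, 1, 50)
        y = 1.0 + 20.0 * x**2 + rng.normal(0, 0.5, x.size)
        assert snowball_compare(SnowballDataset(tuple(zip(x, y)))).preferred_degree == 2
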