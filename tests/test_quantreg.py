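"""Global quantile regression: check loss, sample quantiles, LP fits,
bootstrap inference and standardized coefficients."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leadgwqr import (LinearQuantileRegressor, check_loss, fit_qr,
                      sample_quantile, standardized_fit)
from leadgwqr.quantreg import _solve_qr_lp, _solve_qr_lp_primal

from conftest import COVS


@pytest.mark.parametrize("r,tau,expected", [
    (2.0, 0.75, 1.5),
    (-2.0, 0.75, 0.5),
    (0.0, 0.9, 0.0),
])
def test_check_loss_closed_form(r, tau, expected):
    assert check_loss(r, tau) == pytest.approx(expected)


def test_check_loss_vectorized_and_validates():
    np.testing.assert_allclose(check_loss(np.array([1.0, -1.0]), 0.3),
                               [0.3, 0.7])
    with pytest.raises(ValueError):
        check_loss(1.0, 1.0)


class TestSampleQuantile:
    def test_middle_order_statistic(self):
        assert sample_quantile([1, 2, 3, 4, 5], 0.5) == 3

    def test_flat_optimum_returns_lower_endpoint(self):
        # n*tau integral: the minimising set is [y_(2), y_(3)] = [2, 3]
        assert sample_quantile([4, 1, 3, 2], 0.5) == 2

    def test_matches_brute_force_argmin_over_observations(self):
        rng = np.random.default_rng(42)
        for tau in (0.3, 0.5, 0.77):
            y = rng.normal(size=11)
            losses = [check_loss(y - xi, tau).sum() for xi in y]
            assert sample_quantile(y, tau) == pytest.approx(
                y[int(np.argmin(losses))])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sample_quantile([], 0.5)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40),
           st.floats(0.02, 0.98))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_minimises_check_loss_over_all_observations(self, y, tau):
        """The returned value never loses to any observed candidate, and
        the empirical CDF brackets tau at it (subgradient condition)."""
        y = np.asarray(y)
        q = sample_quantile(y, tau)
        loss_q = check_loss(y - q, tau).sum()
        for cand in y:
            assert loss_q <= check_loss(y - cand, tau).sum() + 1e-7
        n = y.size
        assert (y < q).sum() <= n * tau <= (y <= q).sum() + 1e-9


class TestFitQR:
    def test_intercept_only_reduces_to_sample_quantile(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=11)
        for tau in (0.3, 0.55, 0.77):
            fit = LinearQuantileRegressor(tau=tau, fit_intercept=False).fit(
                np.ones((11, 1)), y)
            assert fit.coef_[0] == pytest.approx(sample_quantile(y, tau),
                                                 abs=1e-9)

    def test_noiseless_line_is_fit_exactly(self):
        x = np.linspace(0, 1, 20)
        y = 1 + 2 * x
        for tau in (0.25, 0.5, 0.9):
            fit = fit_qr(x, y, tau)
            assert fit.intercept_ == pytest.approx(1.0, abs=1e-9)
            assert fit.coef_[0] == pytest.approx(2.0, abs=1e-9)
            assert fit.objective_ == pytest.approx(0.0, abs=1e-9)

    def test_objective_matches_basic_solution_enumeration(self):
        # with one slope the optimum passes through two observations:
        # enumerate every line through a pair of points
        x = np.array([0.1, 0.4, 0.5, 0.9, 1.3, 1.8, 2.2, 2.9])
        y = np.array([0.3, 1.1, 0.2, 1.9, 0.8, 2.6, 1.7, 3.1])
        for tau in (0.25, 0.5, 0.75):
            best = np.inf
            for i in range(8):
                for j in range(i + 1, 8):
                    if x[i] == x[j]:
                        continue
                    b = (y[j] - y[i]) / (x[j] - x[i])
                    a = y[i] - b * x[i]
                    best = min(best,
                               check_loss(y - a - b * x, tau).sum())
            fit = fit_qr(x, y, tau)
            assert fit.objective_ == pytest.approx(best, abs=1e-8)

    def test_dual_and_primal_lp_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            X = np.column_stack([np.ones(40), rng.random((40, 2))])
            y = X @ rng.normal(size=3) + rng.normal(size=40)
            for tau in (0.3, 0.5, 0.8):
                bd = _solve_qr_lp(X, y, tau)
                bp = _solve_qr_lp_primal(X, y, tau)
                assert check_loss(y - X @ bd, tau).sum() == pytest.approx(
                    check_loss(y - X @ bp, tau).sum(), abs=1e-9)

    def test_agrees_with_statsmodels_irls(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        X = rng.random((300, 2))
        y = 0.5 + X @ [1.5, -0.8] + rng.standard_t(4, 300)
        for tau in (0.25, 0.5, 0.9):
            mine = fit_qr(X, y, tau)
            ref = sm.QuantReg(y, sm.add_constant(X)).fit(q=tau)
            np.testing.assert_allclose(mine.beta_, ref.params, atol=1e-4)
            ref_obj = check_loss(y - sm.add_constant(X) @ ref.params,
                                 tau).sum()
            assert mine.objective_ <= ref_obj + 1e-8

    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.75, 0.9])
    def test_subgradient_condition(self, tau):
        rng = np.random.default_rng(int(tau * 100))
        n = 200
        X = rng.random((n, 3))
        y = X @ [1, -2, 0.5] + rng.standard_cauchy(n) * 0.3
        r = fit_qr(X, y, tau).residuals_
        assert (r < -1e-9).sum() <= n * tau
        assert n * tau <= (r <= 1e-9).sum()

    def test_no_random_candidate_beats_the_lp_optimum(self):
        rng = np.random.default_rng(11)
        X = rng.random((50, 2))
        y = X @ [1.0, 2.0] + rng.normal(size=50)
        fit = fit_qr(X, y, 0.5)
        beta = fit.beta_
        D = np.column_stack([np.ones(50), X])
        for _ in range(500):
            cand = beta + rng.normal(size=3) * rng.choice([1e-3, 0.1, 1.0])
            assert check_loss(y - D @ cand, 0.5).sum() >= \
                fit.objective_ - 1e-10

    def test_scale_and_shift_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.random((60, 2))
        y = X @ [2.0, -1.0] + rng.normal(size=60)
        base = fit_qr(X, y, 0.7)
        scaled = fit_qr(X, 3.5 * y, 0.7)
        np.testing.assert_allclose(scaled.beta_, 3.5 * base.beta_, atol=1e-8)
        shifted = fit_qr(X, y + 4.0, 0.7)
        assert shifted.intercept_ == pytest.approx(base.intercept_ + 4.0,
                                                   abs=1e-8)
        np.testing.assert_allclose(shifted.coef_, base.coef_, atol=1e-8)

    def test_rank_deficient_design_names_column(self):
        import pandas as pd
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.random(30)})
        df["b"] = 2.0 * df["a"]  # exact linear dependence
        with pytest.raises(ValueError, match="b"):
            fit_qr(df, rng.random(30), 0.5)


def test_slopes_steepen_with_quantile_under_heteroskedastic_risk(
        calibrated_table):
    """Risk-proportional noise makes covariate effects strengthen toward
    the upper tail: the soil-lead slope grows and the log-tax slope becomes
    more negative as tau rises."""
    X = calibrated_table[COVS]
    y = calibrated_table["rate"].to_numpy()
    soil, tax = [], []
    for tau in (0.25, 0.5, 0.75, 0.9):
        fit = fit_qr(X, y, tau)
        tax.append(fit.coef_[1])
        soil.append(fit.coef_[2])
    assert all(np.diff(soil) > 0)
    assert all(np.diff(tax) < 0)


class TestBootstrapInference:
    def test_noiseless_data_has_zero_se(self):
        x = np.linspace(0, 1, 40)
        y = 1 + 2 * x
        fit = fit_qr(x, y, 0.5).bootstrap_inference(x, y, n_boot=60,
                                                    random_state=0)
        assert np.all(fit.se_ < 1e-9)

    def test_same_seed_reproduces_cis(self):
        rng = np.random.default_rng(9)
        x = rng.random(80)
        y = 1 + 2 * x + rng.normal(size=80)
        f1 = fit_qr(x, y, 0.5).bootstrap_inference(x, y, 60, random_state=3)
        ci1 = (f1.ci_lower_.copy(), f1.ci_upper_.copy())
        f2 = fit_qr(x, y, 0.5).bootstrap_inference(x, y, 60, random_state=3)
        np.testing.assert_array_equal(ci1[0], f2.ci_lower_)
        np.testing.assert_array_equal(ci1[1], f2.ci_upper_)

    def test_too_few_replicates_rejected(self):
        x = np.linspace(0, 1, 30)
        fit = fit_qr(x, x, 0.5)
        with pytest.raises(ValueError):
            fit.bootstrap_inference(x, x, n_boot=10)


class TestStandardizedCoefficients:
    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = X @ [1, -0.5, 0.2] + rng.normal(size=200)
        y = (y - y.mean()) / y.std(ddof=1)
        fit = LinearQuantileRegressor(tau=0.5)
        stb = fit.standardized_coefficients(X, y)
        raw = fit_qr(X, y, 0.5).coef_
        np.testing.assert_allclose(stb, raw, atol=1e-8)

    def test_matches_independent_zscore_refit(self):
        rng = np.random.default_rng(4)
        X = rng.random((150, 2)) * [10, 0.1]
        y = X @ [0.3, -20.0] + rng.normal(size=150)
        stb = standardized_fit(X, y, 0.5)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        oracle = fit_qr(Z, zy, 0.5).coef_
        np.testing.assert_allclose(stb, oracle, atol=1e-9)
        assert np.all(np.sign(stb) == np.sign(fit_qr(X, y, 0.5).coef_))

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        with pytest.raises(ValueError):
            standardized_fit(X, np.arange(30.0), 0.5)
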