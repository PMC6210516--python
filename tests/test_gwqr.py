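"""GWQR engine: kernels, local fits, surfaces, bandwidth selection,
local inference and prediction."""

import numpy as np
import pytest

from leadgwqr import (GWQuantileRegressor, KernelSpec, LinearQuantileRegressor,
                      SyntheticConfig, fit_qr, generate_block_table,
                      kernel_weight)
from leadgwqr.gwqr import fit_gwqr, fit_local, select_bandwidth_aic
from leadgwqr.synthetic import step_surface

from conftest import COVS, design


class TestKernelWeight:
    def test_self_weight_is_one(self):
        for kernel in ("gaussian", "bisquare"):
            assert kernel_weight(0.0, KernelSpec(kernel, 100.0)) == 1.0

    def test_gaussian_closed_form_at_bandwidth(self):
        assert kernel_weight(50.0, KernelSpec("gaussian", 50.0)) == \
            pytest.approx(np.exp(-0.5))

    def test_bisquare_compact_support(self):
        spec = KernelSpec("bisquare", 10.0)
        assert kernel_weight(20.0, spec) == 0.0
        assert kernel_weight(10.0, spec) == 0.0
        assert kernel_weight(5.0, spec) == pytest.approx(0.5625)

    def test_nonincreasing_in_distance(self):
        d = np.linspace(0, 500, 100)
        for kernel in ("gaussian", "bisquare"):
            w = kernel_weight(d, KernelSpec(kernel, 200.0))
            assert np.all(np.diff(w) <= 0)

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            kernel_weight(1.0, KernelSpec("gaussian", 0.0))


class TestFitLocal:
    def test_uniform_weights_reduce_to_global_fit(self, small_table):
        X, y, coords = design(small_table)
        for tau in (0.25, 0.75):
            g = fit_qr(X, y, tau)
            beta, ok, _ = fit_local(X, y, coords, coords[7], tau,
                                    KernelSpec("gaussian", 1e12))
            assert ok
            np.testing.assert_allclose(beta, g.beta_, atol=1e-9)

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 2))
        y = X @ [1, -1] + rng.normal(size=60)
        w = rng.random(60) + 0.2
        b1 = LinearQuantileRegressor(0.5).fit(X, y, sample_weight=w).beta_
        b2 = LinearQuantileRegressor(0.5).fit(X, y, sample_weight=7 * w).beta_
        np.testing.assert_allclose(b1, b2, atol=1e-9)

    def test_distant_clusters_match_per_cluster_fits(self):
        rng = np.random.default_rng(2)
        n = 25
        c_west = rng.uniform(-100, 100, (n, 2))
        c_east = rng.uniform(-100, 100, (n, 2)) + 20000.0
        x_w, x_e = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y_w, y_e = 1 + 2 * x_w, 3 - 1.5 * x_e  # different noiseless slopes
        X = np.concatenate([x_w, x_e])[:, None]
        y = np.concatenate([y_w, y_e])
        coords = np.vstack([c_west, c_east])
        spec = KernelSpec("bisquare", 1000.0)
        for center, xs, ys in [([0, 0], x_w, y_w),
                               ([20000, 20000], x_e, y_e)]:
            beta, ok, _ = fit_local(X, y, coords, center, 0.5, spec)
            assert ok
            np.testing.assert_allclose(beta, fit_qr(xs, ys, 0.5).beta_,
                                       atol=1e-6)

    def test_insufficient_neighbours_flagged_not_converged(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 10000, (12, 2))
        X = rng.random((12, 3))
        y = rng.random(12)
        beta, ok, _ = fit_local(X, y, coords, coords[0], 0.5,
                                KernelSpec("bisquare", 1.0))
        assert not ok
        assert np.isnan(beta).all()


class TestGWQRSurface:
    def test_fitted_quantile_is_rowwise_dot_product(self):
        t = generate_block_table(SyntheticConfig(n_blocks=30, seed=3))
        fit = fit_gwqr(t, 0.5, KernelSpec("gaussian", 3000.0))
        X, _, _ = design(t)
        D = np.column_stack([np.ones(len(t)), X])
        oracle = np.array([D[i] @ fit.local_beta_[i] for i in range(len(t))])
        np.testing.assert_allclose(fit.fitted_quantile_, oracle, atol=1e-12)
        assert fit.fitted_quantile_.mean() == pytest.approx(oracle.mean())

    def test_step_surface_sign_pattern_recovered(self, uncensored_config):
        cfg = SyntheticConfig(
            n_blocks=300, seed=11, coefficient_mode="varying",
            coefficient_surfaces={
                "soil_lead": step_surface(-8e-4, 8e-4, 4000.0)},
            **uncensored_config)
        t = generate_block_table(cfg)
        X, y, coords = design(t)
        fit = GWQuantileRegressor(tau=0.5, kernel="bisquare",
                                  bandwidth=2500.0).fit(X, y, coords)
        truth = np.where(coords[:, 0] < 4000.0, -1.0, 1.0)
        match = np.sign(fit.local_beta_[:, 3]) == truth
        assert match.mean() > 0.9

    def test_all_locations_failing_raises(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 1000, (15, 2))
        X = rng.random((15, 3))
        with pytest.raises(RuntimeError, match="local fit"):
            GWQuantileRegressor(tau=0.5, kernel="bisquare",
                                bandwidth=1e-3).fit(X, rng.random(15), coords)


class TestLocalInference:
    def test_noiseless_surface_has_tiny_se(self):
        rng = np.random.default_rng(6)
        n = 40
        coords = rng.uniform(0, 1000, (n, 2))
        x = rng.random(n)
        y = 1 + 2 * x  # exact local lines everywhere
        fit = GWQuantileRegressor(tau=0.5, bandwidth=500.0).fit(
            x[:, None], y, coords)
        fit.bootstrap_inference(x[:, None], y, n_boot=50, random_state=0)
        assert np.nanmax(fit.local_se_) < 1e-9

    def test_same_seed_reproduces_t_surface(self, uncensored_config):
        cfg = SyntheticConfig(n_blocks=60, seed=7, **uncensored_config)
        t = generate_block_table(cfg)
        X, y, coords = design(t)

        def run():
            f = GWQuantileRegressor(tau=0.5, bandwidth=3000.0).fit(
                X, y, coords)
            f.bootstrap_inference(X, y, n_boot=50, random_state=42)
            return f.local_t_

        np.testing.assert_array_equal(run(), run())

    def test_null_coefficient_rarely_significant(self):
        """Size check: with a truly-zero coefficient in a stationary field,
        few locations should show |t| > 1.96."""
        rng = np.random.default_rng(8)
        n = 150
        coords = rng.uniform(0, 8000, (n, 2))
        X = np.column_stack([rng.random(n), rng.random(n)])
        y = 0.3 + 0.6 * X[:, 0] + 0.0 * X[:, 1] + 0.3 * rng.normal(size=n)
        fit = GWQuantileRegressor(tau=0.5, bandwidth=3000.0).fit(X, y, coords)
        fit.bootstrap_inference(X, y, n_boot=60, random_state=1)
        frac = np.mean(np.abs(fit.local_t_[:, 2]) > 1.96)
        assert frac <= 0.15


class TestBandwidthSelection:
    def test_single_candidate_is_returned(self, small_table):
        X, y, coords = design(small_table)
        sel = select_bandwidth_aic(X, y, coords, 0.5, [4000.0])
        assert sel.chosen_h == 4000.0

    def test_stationary_data_prefers_heavy_smoothing(self, small_table):
        X, y, coords = design(small_table)
        grid = [1500.0, 2500.0, 4000.0, 6500.0, 10000.0]
        sel = select_bandwidth_aic(X, y, coords, 0.5, grid)
        assert sel.chosen_h >= grid[-2]

    def test_varying_coefficients_pull_bandwidth_down(self,
                                                      uncensored_config):
        cfg = SyntheticConfig(
            n_blocks=150, seed=6, coefficient_mode="varying",
            coefficient_surfaces={
                "soil_lead": step_surface(0.0, 1.6e-3, 4000.0)},
            **uncensored_config)
        t = generate_block_table(cfg)
        X, y, coords = design(t)
        grid = [1500.0, 2500.0, 4000.0, 6500.0, 10000.0]
        sel = select_bandwidth_aic(X, y, coords, 0.5, grid)
        assert sel.chosen_h < grid[-1]


class TestPrediction:
    def test_fitted_location_returns_fitted_quantile(self, small_table):
        t = small_table.iloc[:50]
        fit = fit_gwqr(t, 0.5, KernelSpec("gaussian", 3000.0))
        X, _, coords = design(t)
        pred = fit.predict(X[:5], coords[:5])
        np.testing.assert_allclose(pred, fit.fitted_quantile_[:5],
                                   atol=1e-12)

    def test_constant_coefficient_limit_matches_global_prediction(
            self, small_table):
        t = small_table.iloc[:60]
        X, y, coords = design(t)
        fit = fit_gwqr(t.iloc[:50], 0.5, KernelSpec("gaussian", 1e12))
        g = fit_qr(X[:50], y[:50], 0.5)
        pred = fit.predict(X[50:], coords[50:])
        np.testing.assert_allclose(pred, g.predict(X[50:]), atol=1e-6)

    def test_held_out_points_match_independent_refit(self, small_table):
        t = small_table.iloc[:35]
        train, test = t.iloc[:30], t.iloc[30:]
        spec = KernelSpec("gaussian", 2500.0)
        fit = fit_gwqr(train, 0.5, spec)
        Xte, _, cte = design(test)
        pred = fit.predict(Xte, cte)
        Xtr, ytr, ctr = design(train)
        for j in range(len(test)):
            beta, ok, _ = fit_local(Xtr, ytr, ctr, cte[j], 0.5, spec)
            assert ok
            assert pred[j] == pytest.approx(beta[0] + Xte[j] @ beta[1:],
                                            abs=1e-9)

    def test_far_away_point_is_missing_with_warning(self, small_table):
        fit = fit_gwqr(small_table.iloc[:40], 0.5,
                       KernelSpec("gaussian", 1000.0))
        X, _, _ = design(small_table.iloc[:1])
        with pytest.warns(UserWarning, match="3 bandwidths"):
            pred = fit.predict(X, np.array([[1e7, 1e7]]))
        assert np.isnan(pred[0])
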