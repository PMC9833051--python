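"""Point estimators, estimator maps, inverses, and estimate distributions."""

import numpy as np
import pytest
from scipy.stats import ks_2samp, norm

from mogobserver import (
    EstimatorMap,
    MoGPrior,
    approx_inverse,
    bls_estimate,
    build_estimator_map,
    estimate_distribution,
    invert_estimator_map,
    map_estimate,
    posterior_mog,
)
from mogobserver.estimation import bls_estimate_grid
from conftest import random_prior


class TestBLSEstimate:
    def test_single_gaussian_shrinkage(self):
        post = posterior_mog(MoGPrior([1.0], [0.0], [1.5]), np.sqrt(0.75), 3.0)
        assert bls_estimate(post) == pytest.approx(2.25, abs=1e-12)

    def test_symmetric_bimodal_midpoint(self, bimodal_prior):
        for sigma in (0.3, 1.0, 2.5):
            assert abs(bls_estimate(posterior_mog(bimodal_prior, sigma, 0.0))) < 1e-12

    def test_matches_grid_mean_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            prior = random_prior(rng)
            sigma = float(rng.uniform(0.2, 1.5))
            m = float(rng.uniform(-4, 4))
            post = posterior_mog(prior, sigma, m)
            span = np.max(np.abs(post.component_means) + 10 * post.component_sds)
            x = np.linspace(-span, span, 20001)
            dens = post.pdf(x)
            grid_mean = np.trapezoid(x * dens, x) / np.trapezoid(dens, x)
            assert bls_estimate(post) == pytest.approx(grid_mean, abs=1e-8)


class TestMAPEstimate:
    def test_single_gaussian_equals_bls(self):
        post = posterior_mog(MoGPrior([1.0], [1.0], [0.7]), 0.5, 2.0)
        assert map_estimate(post) == bls_estimate(post)

    def test_bimodal_picks_heavier_mode(self):
        prior = MoGPrior([0.7, 0.3], [-2.0, 2.0], [0.5, 0.5])
        post = posterior_mog(prior, 1.0, 0.0)
        est = map_estimate(post, refine_tol=1e-9)
        # dense-grid argmax oracle
        x = np.linspace(-6, 6, 200001)
        oracle = x[np.argmax(post.pdf(x))]
        assert est == pytest.approx(oracle, abs=1e-4)
        assert est < 0

    def test_symmetric_tie_returns_smaller_mode_with_warning(self):
        prior = MoGPrior([0.5, 0.5], [-2.0, 2.0], [0.5, 0.5])
        post = posterior_mog(prior, 1.0, 0.0)
        with pytest.warns(RuntimeWarning, match="tied maxima"):
            est = map_estimate(post)
        assert est < 0


class TestEstimatorMap:
    def test_single_gaussian_map_is_affine(self):
        prior = MoGPrior([1.0], [1.0], [1.2])
        sigma = 0.9
        m_grid = np.linspace(-5, 7, 501)
        emap = build_estimator_map(prior, sigma, m_grid)
        alpha = 1.2**2 / (1.2**2 + sigma**2)
        nt = (sigma**2 / (sigma**2 + 1.2**2)) * 1.0
        np.testing.assert_allclose(emap.xhat_grid, alpha * m_grid + nt, atol=1e-12)
        assert emap.monotone_flag

    def test_flat_prior_limit_is_identity(self):
        emap = build_estimator_map(
            MoGPrior([1.0], [0.0], [100.0]), 0.5, np.linspace(-5, 5, 201)
        )
        assert np.max(np.abs(emap.xhat_grid - emap.m_grid)) < 2e-4

    def test_heavy_tailed_map_is_monotone(self, heavy_prior):
        emap = build_estimator_map(heavy_prior, 0.8, np.linspace(-10, 10, 2001))
        assert emap.monotone_flag

    def test_roundtrip_inversion(self, heavy_prior):
        emap = build_estimator_map(heavy_prior, 0.8)
        for m in (-3.0, 0.4, 2.2):
            xhat = np.interp(m, emap.m_grid, emap.xhat_grid)
            m_back, _ = invert_estimator_map(emap, xhat)
            assert m_back == pytest.approx(m, abs=1e-6)

    def test_single_gaussian_inverse_closed_form(self):
        prior = MoGPrior([1.0], [1.0], [1.2])
        sigma = 0.9
        alpha = 1.2**2 / (1.2**2 + sigma**2)
        nt = (1.0 - alpha) * 1.0
        emap = build_estimator_map(prior, sigma, np.linspace(-6, 8, 2001))
        m, deriv = invert_estimator_map(emap, 1.7)
        assert m == pytest.approx((1.7 - nt) / alpha, abs=1e-9)
        assert deriv == pytest.approx(1.0 / alpha, abs=1e-9)

    def test_inverse_derivative_positive(self, heavy_prior):
        emap = build_estimator_map(heavy_prior, 0.8)
        assert np.all(np.gradient(emap.m_grid, emap.xhat_grid) > 0)

    def test_non_monotone_map_refuses_inversion(self):
        emap = EstimatorMap(
            m_grid=np.array([0.0, 1.0, 2.0]),
            xhat_grid=np.array([0.0, 1.0, 0.5]),
            monotone_flag=False,
            estimator_kind="BLS",
        )
        with pytest.raises(ValueError, match="not strictly increasing"):
            invert_estimator_map(emap, 0.6)

    def test_out_of_range_estimate_raises(self, heavy_prior):
        emap = build_estimator_map(heavy_prior, 0.8)
        with pytest.raises(ValueError, match="range"):
            invert_estimator_map(emap, emap.xhat_grid[-1] + 1.0)

    def test_serializes_to_two_columns(self, tmp_path, heavy_prior):
        emap = build_estimator_map(heavy_prior, 0.8, np.linspace(-2, 2, 11))
        path = tmp_path / "map.tsv"
        emap.to_text(path)
        arr = np.loadtxt(path, skiprows=1)
        assert arr.shape == (11, 2)


class TestApproxInverse:
    def test_single_component_reduces_to_closed_form(self):
        prior = MoGPrior([1.0], [1.0], [1.2])
        sigma = 0.9
        alpha = 1.2**2 / (1.2**2 + sigma**2)
        nt = (1.0 - alpha) * 1.0
        m, deriv = approx_inverse(prior, sigma, x=2.0, xhat=1.7)
        assert m == pytest.approx((1.7 - nt) / alpha, abs=1e-12)
        assert deriv == pytest.approx(1.0 / alpha, abs=1e-12)

    def test_exact_at_expected_measurement(self, heavy_prior):
        # when m = x the frozen weights equal the true weights, so the
        # approximate map agrees with the exact one at T(x)
        sigma, x = 0.8, 1.4
        t_x = bls_estimate(posterior_mog(heavy_prior, sigma, x))
        m, _ = approx_inverse(heavy_prior, sigma, x, t_x)
        assert m == pytest.approx(x, abs=1e-12)

    def test_error_grows_away_from_stimulus(self, heavy_prior):
        sigma, x = 0.8, 1.0
        emap = build_estimator_map(heavy_prior, sigma)
        offsets = np.array([0.5, 1.0, 1.5, 2.0, 2.5]) * sigma
        errs = []
        for dm in offsets:
            m_true = x + dm
            xhat = np.interp(m_true, emap.m_grid, emap.xhat_grid)
            m_approx, _ = approx_inverse(heavy_prior, sigma, x, xhat)
            errs.append(abs(m_approx - m_true))
        assert np.all(np.diff(errs) > 0)


class TestEstimateDistribution:
    def test_exact_sg_centered(self):
        d = estimate_distribution(MoGPrior([1.0], [0.0], [1.0]), 0.5, 0.0, "exact_sg")
        assert d.mean == 0.0

    def test_exact_sg_worked_values(self):
        d = estimate_distribution(
            MoGPrior([1.0], [0.0], [1.5]), np.sqrt(0.75), 3.0, "exact_sg"
        )
        assert d.mean == pytest.approx(2.25, abs=1e-12)
        assert d.sd == pytest.approx(0.75 * np.sqrt(0.75), abs=1e-12)

    def test_exact_sg_rejects_mixture(self, heavy_prior):
        with pytest.raises(ValueError, match="single-Gaussian"):
            estimate_distribution(heavy_prior, 0.5, 1.0, "exact_sg")

    def test_numeric_matches_monte_carlo(self, heavy_prior):
        sigma, x = 0.8, 1.0
        d = estimate_distribution(heavy_prior, sigma, x, "numeric")
        assert d.integral() == pytest.approx(1.0, abs=1e-3)
        rng = np.random.default_rng(3)
        n = 200_000
        samples = bls_estimate_grid(heavy_prior, sigma, x + sigma * rng.normal(size=n))
        mu, sd = d.moments()
        assert samples.mean() == pytest.approx(mu, abs=3 * sd / np.sqrt(n))
        assert samples.std() == pytest.approx(sd, abs=3 * sd / np.sqrt(n))
        # Kolmogorov-Smirnov against inverse-CDF draws from the gridded density
        dx = np.diff(d.support)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * dx * (d.density[1:] + d.density[:-1]))]
        )
        cdf /= cdf[-1]
        synth = np.interp(rng.uniform(size=n), cdf, d.support)
        assert ks_2samp(samples, synth).statistic < 0.01

    def test_all_methods_coincide_for_single_gaussian(self):
        prior = MoGPrior([1.0], [0.5], [1.3])
        sigma, x = 0.7, 2.0
        exact = estimate_distribution(prior, sigma, x, "exact_sg")
        approx = estimate_distribution(prior, sigma, x, "approx")
        numeric = estimate_distribution(prior, sigma, x, "numeric")
        assert approx.mean == pytest.approx(exact.mean, abs=1e-12)
        assert approx.sd == pytest.approx(exact.sd, abs=1e-12)
        grid = np.linspace(exact.mean - 4 * exact.sd, exact.mean + 4 * exact.sd, 101)
        np.testing.assert_allclose(
            numeric.pdf(grid), exact.pdf(grid), rtol=1e-3, atol=1e-6
        )

    def test_approx_mean_equals_exact_bls_at_stimulus(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            prior = random_prior(rng)
            sigma = float(rng.uniform(0.2, 1.5))
            x = float(rng.uniform(-2, 2))
            d = estimate_distribution(prior, sigma, x, "approx")
            assert d.mean == pytest.approx(
                bls_estimate(posterior_mog(prior, sigma, x)), abs=1e-12
            )

    def test_numeric_integrates_to_one_random_observers(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            prior = random_prior(rng)
            sigma = float(rng.uniform(0.2, 1.5))
            x = float(rng.uniform(-2, 2))
            d = estimate_distribution(prior, sigma, x, "numeric")
            assert d.integral() == pytest.approx(1.0, abs=1e-3)
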