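"""2AFC decision rules, psychometric functions, PSE/slope, and bias."""

import numpy as np
import pytest
from scipy.stats import norm

from mogobserver import (
    MoGPrior,
    TwoAFCObserver,
    bias_ratio,
    decision,
    p_yes,
    posterior_exceedance,
    pse_and_slope,
    psychometric_curve,
)
from conftest import random_prior

SQRT_2PI = np.sqrt(2 * np.pi)


class TestPosteriorExceedance:
    def test_exchangeable_measurements_give_half(self, heavy_prior):
        obs = TwoAFCObserver(heavy_prior, 0.8, 0.8)
        assert posterior_exceedance(obs, 1.3, 1.3) == pytest.approx(0.5, abs=1e-12)

    def test_single_gaussian_closed_form(self, sg_prior, worked_observer):
        m1, m2 = 2.0, 3.1
        s1, s2 = worked_observer.sigma1, worked_observer.sigma2
        g2 = 1.5**2
        a1, a2 = g2 / (g2 + s1**2), g2 / (g2 + s2**2)
        expected = norm.cdf(
            (a2 * m2 - a1 * m1) / np.sqrt(a1 * s1**2 + a2 * s2**2)
        )
        assert posterior_exceedance(worked_observer, m1, m2) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_2d_quadrature_oracle(self):
        # brute force: integrate the product posterior above the diagonal
        rng = np.random.default_rng(17)
        for _ in range(3):
            prior = random_prior(rng, max_components=3)
            obs = TwoAFCObserver(
                prior, float(rng.uniform(0.3, 1.2)), float(rng.uniform(0.3, 1.2))
            )
            m1, m2 = rng.uniform(-2, 2, size=2)
            from mogobserver import posterior_mog

            p1 = posterior_mog(prior, obs.sigma1, float(m1))
            p2 = posterior_mog(prior, obs.sigma2, float(m2))
            span = 12.0
            x = np.linspace(-span, span, 1501)
            d1, d2 = p1.pdf(x), p2.pdf(x)
            joint = np.outer(d1, d2)
            above = np.triu(np.ones((x.size, x.size)), k=1) + 0.5 * np.eye(x.size)
            val = np.trapezoid(
                np.trapezoid(joint * above, x, axis=1), x
            )
            assert posterior_exceedance(obs, float(m1), float(m2)) == pytest.approx(
                val, abs=1e-4
            )


class TestDecision:
    def test_tie_gives_no(self, heavy_prior):
        obs = TwoAFCObserver(heavy_prior, 0.8, 0.8)
        assert decision(obs, 2.0, 2.0) == 0  # exceedance exactly 0.5

    def test_single_gaussian_compares_measurements(self, sg_prior):
        obs = TwoAFCObserver(sg_prior, 0.6, 0.6)
        assert decision(obs, 1.0, 1.2) == 1
        assert decision(obs, 1.2, 1.0) == 0

    def test_approx_rule_requires_stimuli(self, heavy_prior):
        obs = TwoAFCObserver(heavy_prior, 0.8, 0.6)
        with pytest.raises(ValueError, match="x1 and x2"):
            decision(obs, 1.0, 1.2, approx=True)
        assert decision(obs, 1.0, 1.2, approx=True, x1=1.0, x2=1.1) in (0, 1)


class TestPYes:
    def test_equal_noise_same_stimuli_is_half(self, heavy_prior, sg_prior):
        for prior in (heavy_prior, sg_prior):
            obs = TwoAFCObserver(prior, 0.8, 0.8)
            assert p_yes(obs, 3.0, 3.0, "numeric") == pytest.approx(0.5, abs=1e-6)

    def test_worked_configuration(self, worked_observer):
        # x1 = x2 = 3, noise variances (0.75, 0.5), gamma = 1.5: the analytic
        # value is Phi(3 (a2 - a1) / sqrt(a1^2 s1^2 + a2^2 s2^2)) ~ 0.593
        pa = p_yes(worked_observer, 3.0, 3.0, "sg_analytic")
        pn = p_yes(worked_observer, 3.0, 3.0, "numeric")
        assert pa == pytest.approx(0.593, abs=1e-3)
        assert pn == pytest.approx(pa, abs=1e-3)

    def test_swapped_noise_gives_complement(self, worked_observer):
        swapped = worked_observer.swapped()
        assert p_yes(swapped, 3.0, 3.0, "sg_analytic") == pytest.approx(
            1.0 - p_yes(worked_observer, 3.0, 3.0, "sg_analytic"), abs=1e-12
        )

    def test_sg_analytic_rejects_mixture(self, heavy_prior):
        with pytest.raises(ValueError, match="single-Gaussian"):
            p_yes(TwoAFCObserver(heavy_prior, 0.5, 0.5), 1.0, 1.0, "sg_analytic")

    def test_numeric_matches_analytic_for_single_gaussian(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            prior = MoGPrior(
                [1.0], [float(rng.uniform(-1, 1))], [float(rng.uniform(0.5, 2.5))]
            )
            obs = TwoAFCObserver(
                prior, float(rng.uniform(0.2, 1.0)), float(rng.uniform(0.2, 1.0))
            )
            x1, x2 = rng.uniform(-2, 3, size=2)
            assert p_yes(obs, x1, x2, "numeric") == pytest.approx(
                p_yes(obs, x1, x2, "sg_analytic"), abs=1e-3
            )

    def test_mog_approx_reduces_to_analytic_at_c1(self):
        prior = MoGPrior([1.0], [0.3], [1.4])
        obs = TwoAFCObserver(prior, 0.9, 0.5)
        for x1, x2 in [(-1.0, 0.5), (2.0, 2.2), (3.0, 1.0)]:
            assert p_yes(obs, x1, x2, "mog_approx") == pytest.approx(
                p_yes(obs, x1, x2, "sg_analytic"), abs=1e-15
            )

    def test_complement_symmetry_all_methods(self, heavy_prior, bimodal_prior):
        rng = np.random.default_rng(9)
        for prior in (heavy_prior, bimodal_prior, random_prior(rng)):
            s1, s2 = rng.uniform(0.3, 1.0, size=2)
            obs = TwoAFCObserver(prior, float(s1), float(s2))
            x1, x2 = rng.uniform(-1.5, 1.5, size=2)
            for method in ("numeric", "mog_approx"):
                total = p_yes(obs, x1, x2, method) + p_yes(
                    obs.swapped(), x2, x1, method
                )
                assert total == pytest.approx(1.0, abs=1e-6)

    def test_sg_curve_strictly_increasing(self, worked_observer):
        curve = psychometric_curve(
            worked_observer, 3.0, np.linspace(0, 6, 31), method="sg_analytic"
        )
        assert np.all(np.diff(curve.p_yes) > 0)
        assert np.all((curve.p_yes >= 0) & (curve.p_yes <= 1))

    def test_curve_serialization(self, tmp_path, worked_observer):
        curve = psychometric_curve(
            worked_observer, 3.0, np.linspace(2, 4, 5), method="sg_analytic"
        )
        path = tmp_path / "curve.tsv"
        curve.to_text(path)
        arr = np.loadtxt(path, skiprows=1)
        assert arr.shape == (5, 3)


class TestPSEAndSlope:
    def test_unbiased_observer_pse_at_reference(self, sg_prior):
        obs = TwoAFCObserver(sg_prior, 0.7, 0.7)
        pse, slope = pse_and_slope(obs, 2.0, "sg_analytic")
        assert pse == pytest.approx(2.0, abs=1e-6)
        assert slope > 0

    def test_worked_pse(self, worked_observer):
        # zero-numerator condition: x2 = x1 alpha1/alpha2 = 3 * 0.75/0.8182
        pse, _ = pse_and_slope(worked_observer, 3.0, "sg_analytic")
        assert pse == pytest.approx(2.75, abs=1e-5)

    def test_slope_formula(self):
        # sigma_diff = 1 should give the standard normal peak density
        prior = MoGPrior([1.0], [0.0], [1e6])  # alpha ~ 1
        obs = TwoAFCObserver(prior, np.sqrt(0.5), np.sqrt(0.5))
        _, slope = pse_and_slope(obs, 0.0, "sg_analytic")
        assert slope == pytest.approx(1.0 / SQRT_2PI, rel=1e-4)

    def test_numeric_and_analytic_slopes_agree_for_sg(self, worked_observer):
        # the analytic slope is per unit of the estimate-difference mean; the
        # numeric central difference is per unit x2, i.e. alpha2 times larger
        pse_a, slope_a = pse_and_slope(worked_observer, 3.0, "sg_analytic")
        pse_n, slope_n = pse_and_slope(worked_observer, 3.0, "numeric")
        alpha2 = 2.25 / (2.25 + worked_observer.sigma2**2)
        assert pse_n == pytest.approx(pse_a, abs=1e-4)
        assert slope_n == pytest.approx(alpha2 * slope_a, rel=1e-3)

    def test_no_crossing_raises_with_diagnostics(self, sg_prior):
        obs = TwoAFCObserver(sg_prior, 0.7, 0.7)
        with pytest.raises(ValueError, match="does not change sign"):
            pse_and_slope(obs, 2.0, "sg_analytic", bracket=(4.0, 6.0))


class TestBiasRatio:
    def test_unbiased_configuration(self, heavy_prior):
        obs = TwoAFCObserver(heavy_prior, 0.8, 0.8)
        assert bias_ratio(obs, 1.3, 1.3) == pytest.approx(1.0, abs=1e-12)

    def test_single_gaussian_worked_value(self, worked_observer):
        assert bias_ratio(worked_observer, 3.0, 3.0) == pytest.approx(
            0.75 / (2.25 / 2.75), abs=1e-12
        )

    def test_limiting_configuration_anchors_range(self):
        # sigma1 -> 0 with all weight effectively on the gamma = 1.1 component
        prior = MoGPrior([1.0], [0.0], [1.1])
        obs = TwoAFCObserver(prior, 1e-6, 1.0)
        expected = 1.0 / (1.21 / 2.21)
        assert bias_ratio(obs, 0.0, 0.0) == pytest.approx(expected, rel=1e-6)

    def test_squared_variant(self, worked_observer):
        r = bias_ratio(worked_observer, 3.0, 3.0)
        assert bias_ratio(worked_observer, 3.0, 3.0, squared=True) == pytest.approx(
            r**2, abs=1e-12
        )
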