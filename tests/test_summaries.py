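"""Posterior summaries against analytic and density-optimization oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from oilab.errors import InputError
from oilab.inference.summarize import (
    PosteriorSummary,
    bf_rope,
    bf_savage_dickey,
    hdi,
    marginal_means,
    pd_direction,
    rope_from_d,
    rope_summary,
    summarize_coefficient,
)


def shortest_interval_from_density(dist, mass=0.95):
    """Density-optimization oracle: minimize ppf(l+mass)-ppf(l) over l."""
    res = optimize.minimize_scalar(
        lambda l: dist.ppf(l + mass) - dist.ppf(l),
        bounds=(1e-9, 1 - mass - 1e-9),
        method="bounded",
    )
    return dist.ppf(res.x), dist.ppf(res.x + mass)


class TestHdi:
    def test_normal_interval_matches_analytic_quantiles(self):
        rng = np.random.default_rng(1)
        lo, hi = hdi(rng.standard_normal(100_000), 0.95)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    @pytest.mark.parametrize("dist", [stats.beta(2, 5), stats.gamma(3), stats.norm(1, 2)])
    def test_matches_density_optimization_oracle(self, dist):
        rng = np.random.default_rng(7)
        samples = dist.rvs(size=400_000, random_state=rng)
        lo, hi = hdi(samples, 0.95)
        olo, ohi = shortest_interval_from_density(dist)
        assert lo == pytest.approx(olo, abs=0.01)
        assert hi == pytest.approx(ohi, abs=0.01)

    def test_constant_samples_give_zero_width(self):
        lo, hi = hdi(np.full(500, 1.7), 0.9)
        assert lo == hi == 1.7

    def test_invalid_mass_rejected(self):
        with pytest.raises(InputError):
            hdi(np.zeros(500), 1.2)


class TestPd:
    def test_one_sided_samples(self):
        assert pd_direction(np.abs(np.random.default_rng(0).standard_normal(1000)) + 0.01) == 100.0

    def test_symmetric_samples_near_half(self):
        x = np.random.default_rng(1).standard_normal(200_000)
        assert pd_direction(x) == pytest.approx(50.0, abs=0.5)

    def test_group_effect_regime(self):
        # N(0.09, 0.033): the strongly-directional regime
        x = np.random.default_rng(2).normal(0.09, 0.033, 200_000)
        expected = 100 * stats.norm.cdf(0.09 / 0.033)
        assert pd_direction(x) == pytest.approx(expected, abs=0.15)

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_invariant_to_positive_scaling(self, scale):
        x = np.random.default_rng(3).normal(0.2, 1.0, 5000)
        assert pd_direction(x) == pd_direction(scale * x)


class TestRope:
    def test_point_and_outside_masses(self):
        rope = (-0.013, 0.013)
        assert rope_summary(np.zeros(1000), rope) == 100.0
        assert rope_summary(np.full(1000, 0.03), rope) == 0.0
        inside = np.random.default_rng(0).uniform(-0.013, 0.013, 1000)
        assert rope_summary(inside, rope) == 100.0

    def test_rope_from_negligible_effect_size(self):
        assert rope_from_d(0.007) == 0.013
        assert rope_from_d(0.0) == 0.0
        assert rope_from_d(0.1) == 0.181  # 0.1 * pi/sqrt(3)
        with pytest.raises(InputError):
            rope_from_d(-0.1)


class TestBayesFactors:
    def test_posterior_equal_to_prior_gives_bf_one(self):
        rng = np.random.default_rng(4)
        prior = stats.norm(0, 1)
        samples = prior.rvs(size=100_000, random_state=rng)
        bf, capped = bf_savage_dickey(samples, prior.pdf(0))
        assert not capped
        assert bf == pytest.approx(1.0, rel=0.05)
        bfr, capped_r = bf_rope(samples, prior, (-0.013, 0.013))
        assert not capped_r
        assert bfr == pytest.approx(1.0, rel=0.05)

    def test_matches_conjugate_normal_closed_form(self):
        # y_i ~ N(theta, 1), theta ~ N(0,1): posterior N(n*ybar/(n+1), 1/(n+1))
        rng = np.random.default_rng(5)
        for rep in range(20):
            n = int(rng.integers(10, 40))
            post_sd = 1.0 / np.sqrt(n + 1)
            post_mean = float(rng.uniform(-1.0, 1.0)) * post_sd
            samples = rng.normal(post_mean, post_sd, 40_000)
            exact = stats.norm(0, 1).pdf(0) / stats.norm(post_mean, post_sd).pdf(0)
            bf, capped = bf_savage_dickey(samples, stats.norm(0, 1).pdf(0))
            assert not capped
            assert bf == pytest.approx(exact, rel=0.05)

    def test_effect_far_outside_rope_gives_large_bf(self):
        rng = np.random.default_rng(6)
        samples = rng.normal(0.5, 0.05, 20_000)
        bfr, _ = bf_rope(samples, stats.norm(0, 0.3), (-0.013, 0.013))
        assert bfr > 10

    def test_point_bf_caps_and_flags_when_density_underflows(self):
        samples = np.random.default_rng(7).normal(30.0, 0.5, 10_000)
        bf, capped = bf_savage_dickey(samples, stats.norm(0, 1).pdf(0))
        assert capped and bf == pytest.approx(1e4)


class TestSummaryContainer:
    @given(st.integers(0, 10_000))
    def test_median_always_inside_hdi(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), 2000)
        s = summarize_coefficient("b", x, prior_sd=None)
        assert s.hdi_low <= s.median <= s.hdi_high
        assert 50.0 <= s.pd <= 100.0
        assert 0.0 <= s.pct_in_rope <= 100.0

    def test_invalid_summary_rejected(self):
        with pytest.raises(InputError):
            PosteriorSummary(name="b", median=1.0, hdi_low=0.0, hdi_high=0.5, pd=90.0)

    def test_report_line_format(self):
        x = np.random.default_rng(0).normal(0.09, 0.03, 4000)
        line = summarize_coefficient("prev_outcome", x).report_line()
        assert "median 0.09" in line and "OR 1.09" in line


class TestMarginalMeans:
    def test_point_draw_closed_form(self):
        class PointDraws:
            names = ["intercept", "prev_outcome"]

            def samples(self, name):
                return np.full(200, -0.14 if name == "intercept" else 0.12)

        m = marginal_means(PointDraws())
        assert m[0]["median"] == pytest.approx(1 / (1 + np.exp(0.20)), abs=1e-9)
        assert m[1]["median"] == pytest.approx(1 / (1 + np.exp(0.08)), abs=1e-9)

    def test_zero_coefficients_predict_half(self):
        class ZeroDraws:
            names = ["intercept", "prev_outcome"]

            def samples(self, name):
                return np.zeros(200)

        m = marginal_means(ZeroDraws())
        assert m[0]["median"] == 0.5 == m[1]["median"]
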