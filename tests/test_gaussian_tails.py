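"""Numerical kernel: truncated-normal moments and bivariate tail probabilities.

Oracles used here are independent of the implementation paths they check:
the complementary error function for tails, scipy.stats.truncnorm and seeded
rejection-sampling Monte-Carlo for truncated moments, and adaptive quadrature
of the conditional-normal form plus scipy's multivariate normal CDF for the
bivariate rectangle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate
from scipy.special import ndtr
from scipy.stats import multivariate_normal, norm, truncnorm

from trialcost import (
    NEG_INF,
    DegenerateTruncationError,
    InvalidParameterError,
    ScreeningModel,
    bvn_upper_rect,
    cond_upper,
    trunc_mean,
    trunc_var,
    upper_tail,
)


def bvn_quadrature(u: float, v: float, rho: float) -> float:
    """Independent oracle: integrate phi(t) * Phi((rho*t - u)/sqrt(1-rho^2))."""
    s = math.sqrt(1.0 - rho * rho)
    val, _ = integrate.quad(
        lambda t: norm.pdf(t) * ndtr((rho * t - u) / s), v, 9.0,
        epsabs=1e-13, limit=200,
    )
    return val


class TestUpperTail:
    @pytest.mark.parametrize(
        "mu, sd, a, expected",
        [
            (5.0, 2.0, 5.0, 0.5),                      # symmetry at the mean
            (5.0, 2.0, NEG_INF, 1.0),                  # whole support
            (5.0, 2.0, 7.0, 0.5 * math.erfc(1.0 / math.sqrt(2.0))),  # erfc oracle
        ],
    )
    def test_examples(self, mu, sd, a, expected):
        assert upper_tail(mu, sd, a) == pytest.approx(expected, abs=1e-12)

    def test_invalid_sd(self):
        with pytest.raises(InvalidParameterError):
            upper_tail(0.0, 0.0, 1.0)

    def test_nonincreasing_in_threshold(self):
        grid = np.linspace(-3, 13, 100)
        vals = [upper_tail(5.0, 2.0, a) for a in grid]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))


class TestTruncatedMoments:
    def test_no_truncation(self):
        assert trunc_mean(5.0, 2.0, NEG_INF) == 5.0
        assert trunc_var(0.0, 1.0, NEG_INF) == 1.0

    def test_half_normal_closed_forms(self):
        assert trunc_mean(0.0, 1.0, 0.0) == pytest.approx(math.sqrt(2.0 / math.pi),
                                                          abs=1e-12)
        assert trunc_var(0.0, 1.0, 0.0) == pytest.approx(1.0 - 2.0 / math.pi,
                                                         abs=1e-12)

    @pytest.mark.parametrize("a", [5.3, 1.0, 8.0])
    def test_matches_truncnorm(self, a):
        mu, sd = 5.0, 2.0
        dist = truncnorm((a - mu) / sd, np.inf, loc=mu, scale=sd)
        assert trunc_mean(mu, sd, a) == pytest.approx(dist.mean(), rel=1e-9)
        assert trunc_var(mu, sd, a) == pytest.approx(dist.var(), rel=1e-9)

    @pytest.mark.parametrize("a", [5.0 - 2 * 2.0, 5.0, 5.0 + 1.5 * 2.0])
    def test_matches_rejection_sampling(self, a):
        """Seeded 1e6-draw rejection-sampling oracle, 4-standard-error band."""
        mu, sd = 5.0, 2.0
        rng = np.random.default_rng(20260925)
        draws = mu + sd * rng.standard_normal(1_000_000)
        kept = draws[draws >= a]
        m = kept.size
        mean_se = kept.std(ddof=1) / math.sqrt(m)
        assert trunc_mean(mu, sd, a) == pytest.approx(kept.mean(), abs=4 * mean_se)
        dev2 = (kept - kept.mean()) ** 2
        var_se = dev2.std(ddof=1) / math.sqrt(m)
        assert trunc_var(mu, sd, a) == pytest.approx(kept.var(ddof=1), abs=4 * var_se)

    def test_monotone_over_threshold_grid(self):
        grid = np.linspace(-1.0, 11.0, 100)
        means = np.array([trunc_mean(5.0, 2.0, a) for a in grid])
        vars_ = np.array([trunc_var(5.0, 2.0, a) for a in grid])
        assert np.all(np.diff(means) >= -1e-10)
        assert np.all(np.diff(vars_) <= 1e-10)
        assert np.all(means >= np.maximum(5.0, grid))
        assert np.all((vars_ > 0) & (vars_ <= 4.0 + 1e-12))

    def test_degenerate_truncation(self):
        with pytest.raises(DegenerateTruncationError):
            trunc_mean(0.0, 1.0, 9.0)
        with pytest.raises(DegenerateTruncationError):
            trunc_var(0.0, 1.0, 9.0)


class TestBivariateUpperRectangle:
    def test_independence_reduces_to_product(self):
        assert bvn_upper_rect(0.4, -1.2, 0.0) == pytest.approx(
            ndtr(-0.4) * ndtr(1.2), abs=1e-14
        )

    def test_orthant_closed_form(self):
        expected = 0.25 + math.asin(0.7) / (2 * math.pi)
        assert bvn_upper_rect(0.0, 0.0, 0.7) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "u, v, rho",
        [
            (0.4, 0.0, 0.7),
            (1.2, -0.3, 0.5),
            (-2.0, 1.0, 0.9),
            (0.5, 0.5, -0.6),
            (0.0, 1.3, 0.3),
            (2.5, 2.5, 0.99),
        ],
    )
    def test_matches_quadrature_and_scipy(self, u, v, rho):
        got = bvn_upper_rect(u, v, rho)
        assert got == pytest.approx(bvn_quadrature(u, v, rho), abs=1e-10)
        rv = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        assert got == pytest.approx(rv.cdf([-u, -v]), abs=1e-8)

    def test_worked_value(self):
        # frozen from the quadrature oracle (also matches R mvtnorm::pmvnorm)
        assert bvn_upper_rect(0.4, 0.0, 0.7) == pytest.approx(0.2838527070, abs=1e-9)

    def test_matches_monte_carlo(self):
        rho = 0.7
        rng = np.random.default_rng(7)
        e = rng.standard_normal((2, 1_000_000))
        u_draw, v_draw = e[0], rho * e[0] + math.sqrt(1 - rho**2) * e[1]
        hit = (u_draw >= 0.4) & (v_draw >= 0.0)
        p_hat = hit.mean()
        se = math.sqrt(p_hat * (1 - p_hat) / hit.size)
        assert bvn_upper_rect(0.4, 0.0, rho) == pytest.approx(p_hat, abs=4 * se)

    def test_infinite_bounds(self):
        assert bvn_upper_rect(NEG_INF, NEG_INF, 0.5) == 1.0
        assert bvn_upper_rect(NEG_INF, 0.7, 0.5) == pytest.approx(ndtr(-0.7), abs=1e-14)
        assert bvn_upper_rect(0.7, NEG_INF, 0.5) == pytest.approx(ndtr(-0.7), abs=1e-14)

    def test_invalid_rho(self):
        with pytest.raises(InvalidParameterError):
            bvn_upper_rect(0.0, 0.0, 1.0)

    @given(
        u=st.floats(-4, 4),
        v=st.floats(-4, 4),
        rho=st.floats(-0.99, 0.99),
    )
    def test_symmetry_bounds_and_inclusion_exclusion(self, u, v, rho):
        p = bvn_upper_rect(u, v, rho)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(bvn_upper_rect(v, u, rho), abs=1e-12)
        # P(U>=u) + P(V>=v) - P(U>=u or V>=v) reconstructs the rectangle
        union = 1.0 - bvn_upper_rect(-u, -v, rho)  # 1 - P(U<u, V<v) by symmetry
        assert p == pytest.approx(float(ndtr(-u) + ndtr(-v)) - union, abs=1e-8)


class TestConditionalUpper:
    def test_no_prescreen_reduces_to_marginal(self, screening):
        a = 5.8
        assert cond_upper(screening, a, NEG_INF) == pytest.approx(
            upper_tail(5.0, 2.0, a), abs=1e-12
        )

    def test_independent_surrogate_is_uninformative(self):
        model = ScreeningModel(5.0, 2.0, 5.0, 2.0, rho=0.0)
        for b in (-1.0, 5.0, 7.5):
            assert cond_upper(model, 5.8, b) == pytest.approx(
                upper_tail(5.0, 2.0, 5.8), abs=1e-12
            )

    def test_worked_value(self, screening):
        # ratio of the frozen rectangle oracle to P(Z >= 5) = 1/2
        assert cond_upper(screening, 5.8, 5.0) == pytest.approx(
            0.2838527070 / 0.5, abs=2e-9
        )

    def test_nondecreasing_in_prescreen_cut(self, screening):
        bs = np.linspace(-1.0, 10.0, 60)
        vals = [cond_upper(screening, 5.8, b) for b in bs]
        assert all(later >= earlier - 1e-12
                   for earlier, later in zip(vals, vals[1:]))

    def test_degenerate_prescreen(self, screening):
        with pytest.raises(DegenerateTruncationError):
            cond_upper(screening, 5.8, 5.0 + 2.0 * 9.0)
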