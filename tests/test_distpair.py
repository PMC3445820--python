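import math

import numpy as np
import pytest
from scipy import stats

from skewsim.distpair import (
    DistributionPair,
    MemberParams,
    make_pair,
    prob_x_less_y,
    sample_pair,
    solve_gamma_shape,
    solve_lognormal_sigma,
)

SKEWS = [1.0, 2.0, 3.0, 4.0]
RATIOS = [1.05, 1.10, 1.15, 1.20, 1.25, 1.30, 1.40, 1.50]


def _sample_skewness(draws: np.ndarray) -> float:
    c = draws - draws.mean()
    return (c**3).mean() / (c**2).mean() ** 1.5


class TestSolveGammaShape:
    def test_exponential_case(self):
        # skewness 2 is the exponential distribution
        assert solve_gamma_shape(2.0) == 1.0

    @pytest.mark.parametrize("skew,expected", [(1.0, 4.0), (4.0, 0.25)])
    def test_closed_form(self, skew, expected):
        assert solve_gamma_shape(skew) == pytest.approx(expected, rel=1e-14)

    @pytest.mark.parametrize("skew", [1.0, 4.0])
    def test_monte_carlo_skewness(self, skew, rng):
        k = solve_gamma_shape(skew)
        draws = rng.gamma(k, 1.0, size=10_000_000)
        # SE of the sample skewness of a gamma is approx sqrt(6/n)-scale but
        # heavy-tailed; a generous absolute band suffices at 10^7 draws
        assert _sample_skewness(draws) == pytest.approx(skew, abs=0.05)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            solve_gamma_shape(bad)


class TestSolveLognormalSigma:
    def test_exact_root_skew4(self):
        # (w+2)^2 (w-1) = 16 has exact root w = 2 -> sigma = sqrt(ln 2)
        assert solve_lognormal_sigma(4.0) == pytest.approx(math.sqrt(math.log(2.0)), rel=1e-12)

    def test_skew1_against_bisection_oracle(self):
        # frozen from an independent 200-step bisection of (w+2)*sqrt(w-1)=1
        assert solve_lognormal_sigma(1.0) == pytest.approx(0.3142639889725941, rel=1e-10)

    def test_small_skew_limit(self):
        assert solve_lognormal_sigma(1e-6) < 1e-3

    @pytest.mark.parametrize("skew", SKEWS + [0.5, 10.0, 100.0])
    def test_roundtrip(self, skew):
        sigma = solve_lognormal_sigma(skew)
        w = math.exp(sigma**2)
        assert (w + 2.0) * math.sqrt(w - 1.0) == pytest.approx(skew, rel=1e-10)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            solve_lognormal_sigma(-2.0)


class TestMakePair:
    @pytest.mark.parametrize("family", ["gamma", "lognormal"])
    @pytest.mark.parametrize("skew", SKEWS)
    @pytest.mark.parametrize("ratio", [1.0] + RATIOS)
    def test_moment_invariants(self, family, skew, ratio):
        pair = make_pair(family, skew, ratio)
        assert pair.y.sd == pytest.approx(1.0, rel=1e-12)
        assert pair.x.mean == pytest.approx(pair.y.mean, rel=1e-10)
        assert pair.x.sd / pair.y.sd == pytest.approx(ratio, rel=1e-10)
        # shared shape parameter makes the skewness match exact
        assert pair.x.shape == pair.y.shape
        assert pair.x.skewness == pytest.approx(skew, rel=1e-10)
        assert pair.y.skewness == pytest.approx(skew, rel=1e-10)

    def test_ratio_one_is_identity(self):
        pair = make_pair("gamma", 3.0, 1.0)
        assert pair.x == pair.y
        assert pair.x.shift == 0.0

    def test_larger_sd_member_is_shifted_down(self):
        pair = make_pair("gamma", 2.0, 1.25)
        assert pair.x.shift < 0.0
        assert pair.y.shift == 0.0

    def test_lognormal_moments_against_monte_carlo(self, rng):
        pair = make_pair("lognormal", 2.0, 1.25)
        x, y = sample_pair(pair, 10_000_000, rng)
        se_mean = pair.x.sd / math.sqrt(x.size)
        assert x.mean() - y.mean() == pytest.approx(0.0, abs=4 * se_mean * math.sqrt(2))
        assert x.std(ddof=1) / y.std(ddof=1) == pytest.approx(1.25, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_pair("normal", 1.0, 1.1)
        with pytest.raises(ValueError):
            make_pair("gamma", 1.0, 0.9)
        with pytest.raises(ValueError):
            make_pair("gamma", -1.0, 1.1)


class TestMemberParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            MemberParams("gamma", shape=-1.0, scale=1.0)
        with pytest.raises(ValueError):
            MemberParams("gamma", shape=1.0, scale=0.0)
        with pytest.raises(ValueError):
            MemberParams("weird", shape=1.0, scale=1.0)

    def test_exponential_pdf_closed_form(self):
        member = MemberParams("gamma", shape=1.0, scale=1.0, shift=0.0)
        t = np.linspace(0.0, 10.0, 50)
        np.testing.assert_allclose(member.pdf(t), np.exp(-t), rtol=1e-12)

    @pytest.mark.parametrize("family", ["gamma", "lognormal"])
    def test_pdf_normalization_and_cdf_limits(self, family):
        # skewness 1.5 keeps the gamma shape above 1 so the pdf is bounded
        # and a trapezoid integral is an independent check
        pair = make_pair(family, 1.5, 1.3)
        for member in (pair.x, pair.y):
            grid = np.linspace(member.support_lower, member.ppf(1 - 1e-12), 200_001)
            mass = np.trapezoid(member.pdf(grid), grid)
            assert mass == pytest.approx(1.0, abs=1e-4)
            assert member.cdf(member.support_lower - 1.0) == 0.0
            assert member.cdf(1e12) == pytest.approx(1.0, abs=1e-12)

    def test_singular_pdf_integrates_to_cdf(self):
        # gamma shape < 1: pdf unbounded at the support edge, but its
        # integral over [edge, q] must still equal cdf(q)
        from scipy import integrate

        member = make_pair("gamma", 4.0, 1.2).x  # shape 0.25
        q = member.ppf(0.7)
        mass, _ = integrate.quad(member.pdf, member.support_lower, q, points=[member.support_lower])
        assert mass == pytest.approx(0.7, abs=1e-8)

    def test_lognormal_median(self):
        member = MemberParams("lognormal", shape=0.5, scale=2.0, shift=3.0)
        median = member.shift + member.scale  # shift + exp(mu)
        assert member.cdf(median) == pytest.approx(0.5, abs=1e-12)
        assert member.ppf(0.5) == pytest.approx(median, rel=1e-10)

    def test_shift_moves_support(self):
        member = MemberParams("gamma", shape=2.0, scale=1.0, shift=-5.0)
        assert member.cdf(-5.5) == 0.0
        assert member.mean == pytest.approx(-3.0, rel=1e-12)


class TestSamplePair:
    def test_determinism(self):
        pair = make_pair("gamma", 3.0, 1.2)
        x1, y1 = sample_pair(pair, 100, np.random.default_rng(7))
        x2, y2 = sample_pair(pair, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)

    def test_blocked_equals_sequential(self):
        # row i of a blocked draw matches the i-th sequential call
        pair = make_pair("lognormal", 2.0, 1.4)
        xb, yb = sample_pair(pair, 25, np.random.default_rng(3), size=6)
        rng = np.random.default_rng(3)
        for i in range(6):
            x, y = sample_pair(pair, 25, rng)
            np.testing.assert_array_equal(xb[i], x)
            np.testing.assert_array_equal(yb[i], y)

    def test_sample_skewness(self, rng):
        pair = make_pair("gamma", 3.0, 1.1)
        x, _ = sample_pair(pair, 1_000_000, rng)
        assert _sample_skewness(x) == pytest.approx(3.0, abs=0.1)

    def test_ratio_one_same_distribution(self, rng):
        pair = make_pair("gamma", 2.0, 1.0)
        x, y = sample_pair(pair, 50_000, rng)
        assert stats.ks_2samp(x, y).pvalue > 0.001

    def test_n_validation(self, rng):
        with pytest.raises(ValueError):
            sample_pair(make_pair("gamma", 1.0, 1.1), 0, rng)


class TestProbXLessY:
    def test_ratio_one_is_half(self):
        for family in ("gamma", "lognormal"):
            assert prob_x_less_y(make_pair(family, 2.0, 1.0)) == pytest.approx(0.5, abs=1e-8)

    @pytest.mark.parametrize(
        "family,skew,ratio,expected",
        [
            ("gamma", 3.0, 1.10, 0.56),
            ("gamma", 4.0, 1.50, 0.68),
            ("lognormal", 3.0, 1.10, 0.52),
            ("gamma", 1.0, 1.05, 0.50),
            ("lognormal", 4.0, 1.50, 0.58),
        ],
    )
    def test_published_cells(self, family, skew, ratio, expected):
        p = prob_x_less_y(make_pair(family, skew, ratio))
        assert round(p, 2) == expected

    @pytest.mark.parametrize("family", ["gamma", "lognormal"])
    @pytest.mark.parametrize("skew", SKEWS)
    def test_nondecreasing_in_sd_ratio(self, family, skew):
        probs = [prob_x_less_y(make_pair(family, skew, r)) for r in RATIOS]
        assert all(b >= a - 1e-10 for a, b in zip(probs, probs[1:]))

    @pytest.mark.parametrize(
        "family,skew,ratio",
        [("gamma", 4.0, 1.5), ("gamma", 1.0, 1.05), ("lognormal", 3.0, 1.25)],
    )
    def test_against_monte_carlo(self, family, skew, ratio, rng):
        pair = make_pair(family, skew, ratio)
        x, y = sample_pair(pair, 10_000_000, rng)
        p_hat = float(np.mean(x < y))
        se = math.sqrt(p_hat * (1 - p_hat) / x.size)
        assert prob_x_less_y(pair) == pytest.approx(p_hat, abs=3 * se)


class TestDistributionPairValidation:
    def test_mixed_family_rejected(self):
        g = MemberParams("gamma", 1.0, 1.0)
        l = MemberParams("lognormal", 1.0, 1.0)
        with pytest.raises(ValueError):
            DistributionPair(x=g, y=l, skewness=2.0, sd_ratio=1.1, common_mean=1.0)

    def test_ratio_below_one_rejected(self):
        g = MemberParams("gamma", 1.0, 1.0)
        with pytest.raises(ValueError):
            DistributionPair(x=g, y=g, skewness=2.0, sd_ratio=0.5, common_mean=1.0)
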