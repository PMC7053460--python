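"""Unit and property tests for the generic FRL-X transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from frlx import (
    FRLXParams,
    ResidualLifeQuery,
    characterization_check,
    frlx_cdf,
    frlx_hazard,
    frlx_mgf,
    frlx_moment,
    frlx_pdf,
    frlx_quantile,
    frlx_rvs,
    frlx_sf,
    ks_pvalue,
    ks_statistic,
    residual_life_sf,
    reverse_residual_life_sf,
    weibull_baseline,
)

BASE = weibull_baseline()

params_strategy = st.tuples(
    st.floats(0.5, 3.0), st.floats(0.1, 5.0), st.floats(0.2, 3.0)
).map(lambda t: FRLXParams(sigma=t[1], xi=(t[0], t[2])))


def quad_pdf(params, lo=0.0, hi=np.inf):
    return integrate.quad(lambda t: float(frlx_pdf(t, params, BASE)), lo, hi,
                          limit=200)[0]


class TestCdfPdf:
    def test_cdf_at_support_ends(self, frlw_params):
        assert frlx_cdf(0.0, frlw_params, BASE) == 0.0
        assert frlx_cdf(1e9, frlw_params, BASE) == pytest.approx(1.0, abs=1e-12)

    def test_cdf_half_baseline_level_sigma_one(self, base):
        # F(x) = 1/2 at x = log 2 for the unit exponential special case
        params = FRLXParams(sigma=1.0, xi=(1.0, 1.0))
        expected = 1.0 - math.log(1.5) / math.log(2.0)
        assert frlx_cdf(math.log(2.0), params, base) == pytest.approx(expected, abs=1e-15)

    def test_invalid_sigma_rejected(self):
        for bad in (0.0, -1.0, float("nan")):
            with pytest.raises(ValueError):
                FRLXParams(sigma=bad, xi=(1.0, 1.0))

    def test_pdf_zero_outside_support(self, frlw_params):
        assert frlx_pdf(-1.0, frlw_params, BASE) == 0.0

    def test_pdf_integrates_to_one(self, frlw_params):
        assert quad_pdf(frlw_params) == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params=params_strategy)
    def test_pdf_normalization_random_params(self, params):
        assert quad_pdf(params) == pytest.approx(1.0, abs=1e-6)

    def test_pdf_matches_cdf_derivative(self, frlw_params):
        h = 1e-6
        for x in (0.3, 1.0, 2.7, 6.0):
            num = (frlx_cdf(x + h, frlw_params, BASE)
                   - frlx_cdf(x - h, frlw_params, BASE)) / (2 * h)
            assert num == pytest.approx(frlx_pdf(x, frlw_params, BASE), rel=1e-6)

    def test_cdf_nondecreasing(self, frlw_params):
        x = np.linspace(0.0, 20.0, 500)
        assert np.all(np.diff(frlx_cdf(x, frlw_params, BASE)) >= 0)

    def test_sigma_one_reduces_to_log_transformed_family(self, base):
        """With sigma = 1 the cdf is exactly 1 - log(2 - F)/log 2."""
        params = FRLXParams(sigma=1.0, xi=(0.7, 0.4))
        x = np.linspace(0.01, 15.0, 200)
        F = base.cdf(x, params.xi)
        expected = 1.0 - np.log(2.0 - F) / math.log(2.0)
        np.testing.assert_allclose(frlx_cdf(x, params, base), expected, atol=1e-14)

    def test_sigma_to_zero_recovers_baseline(self, base):
        params = FRLXParams(sigma=1e-8, xi=(0.7, 0.4))
        x = np.linspace(0.01, 15.0, 200)
        assert np.max(np.abs(frlx_cdf(x, params, base) - base.cdf(x, params.xi))) < 1e-6


class TestSurvivalHazard:
    def test_sf_complements_cdf(self, frlw_params):
        x = np.linspace(0.0, 12.0, 100)
        np.testing.assert_allclose(
            frlx_sf(x, frlw_params, BASE) + frlx_cdf(x, frlw_params, BASE), 1.0,
            atol=1e-12,
        )

    def test_hazard_is_pdf_over_sf(self, frlw_params):
        x = np.linspace(0.05, 8.0, 50)
        np.testing.assert_allclose(
            frlx_hazard(x, frlw_params, BASE),
            frlx_pdf(x, frlw_params, BASE) / frlx_sf(x, frlw_params, BASE),
            rtol=1e-10,
        )

    def test_hazard_infinite_when_sf_vanishes(self):
        # Baseline with finite support exhausted: F = 1 within float precision
        params = FRLXParams(sigma=1.3, xi=(2.0, 1.0))
        assert frlx_hazard(1e4, params, BASE) == np.inf

    def test_cumulative_hazard_matches_log_survival(self, frlw_params):
        for x in (0.5, 2.0, 5.0):
            cum, _ = integrate.quad(
                lambda u: float(frlx_hazard(u, frlw_params, BASE)), 0.0, x, limit=200
            )
            assert cum == pytest.approx(-math.log(frlx_sf(x, frlw_params, BASE)),
                                        rel=1e-6)


class TestQuantileSampling:
    def test_round_trip_example(self, frlw_params):
        q = frlx_quantile(0.37, frlw_params, BASE)
        assert abs(frlx_cdf(q, frlw_params, BASE) - 0.37) < 1e-9

    def test_inversion_grid(self, frlw_params):
        u = np.arange(0.01, 1.0, 0.01)
        back = frlx_cdf(frlx_quantile(u, frlw_params, BASE), frlw_params, BASE)
        np.testing.assert_allclose(back, u, atol=1e-9)

    def test_endpoints_map_to_support(self, frlw_params):
        assert frlx_quantile(0.0, frlw_params, BASE) == 0.0
        assert frlx_quantile(1.0, frlw_params, BASE) == np.inf

    def test_out_of_range_levels_rejected(self, frlw_params):
        for bad in (-0.1, 1.1, np.nan):
            with pytest.raises(ValueError):
                frlx_quantile(bad, frlw_params, BASE)

    def test_rvs_deterministic_given_seed(self, frlw_params):
        a = frlx_rvs(100, frlw_params, BASE, seed=42)
        b = frlx_rvs(100, frlw_params, BASE, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_rvs_rejects_bad_sizes(self, frlw_params):
        with pytest.raises(ValueError):
            frlx_rvs(0, frlw_params, BASE, seed=1)

    def test_rvs_distribution_self_consistent(self, frlw_params):
        """Large inverse-transform sample is not rejected against its own cdf."""
        x = frlx_rvs(100_000, frlw_params, BASE, seed=5)
        ks = ks_statistic(np.sort(frlx_cdf(x, frlw_params, BASE)))
        assert ks_pvalue(ks, x.size) > 0.01

    def test_rvs_mean_matches_first_moment(self, frlw_params):
        x = frlx_rvs(100_000, frlw_params, BASE, seed=6)
        mu = frlx_moment(1, frlw_params, BASE)
        se = x.std() / math.sqrt(x.size)
        assert abs(x.mean() - mu) < 3 * se


class TestMoments:
    def test_zeroth_moment_is_one(self, frlw_params):
        assert frlx_moment(0, frlw_params, BASE) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_series_agrees_with_quadrature(self, frlw_params, r):
        s = frlx_moment(r, frlw_params, BASE, method="series")
        q = frlx_moment(r, frlw_params, BASE, method="quadrature")
        assert s == pytest.approx(q, rel=1e-6)

    def test_variance_nonnegative(self, frlw_params):
        m1 = frlx_moment(1, frlw_params, BASE)
        m2 = frlx_moment(2, frlw_params, BASE)
        assert m2 - m1**2 >= 0

    def test_invalid_order_rejected(self, frlw_params):
        with pytest.raises(ValueError):
            frlx_moment(-1, frlw_params, BASE)
        with pytest.raises(ValueError):
            frlx_moment(1, frlw_params, BASE, method="magic")


class TestMgf:
    LIGHT = FRLXParams(sigma=1.3, xi=(1.5, 0.8))  # light tail: mgf exists near 0

    def test_value_at_zero(self):
        assert frlx_mgf(0.0, self.LIGHT, BASE) == 1.0

    def test_taylor_limit_gives_first_moment(self):
        m1 = frlx_moment(1, self.LIGHT, BASE)
        t = 1e-4
        assert (frlx_mgf(t, self.LIGHT, BASE) - 1.0) / t == pytest.approx(
            m1, abs=5 * t * frlx_moment(2, self.LIGHT, BASE)
        )

    def test_matches_quadrature(self):
        t = 0.3

        def integrand(x):
            lp = float(np.log(frlx_pdf(x, self.LIGHT, BASE)))
            return math.exp(t * x + lp) if np.isfinite(lp) else 0.0

        ref, _ = integrate.quad(integrand, 0, np.inf, limit=200)
        assert frlx_mgf(t, self.LIGHT, BASE) == pytest.approx(ref, rel=1e-6)

    def test_divergence_signalled_for_heavy_tail(self, frlw_params):
        # Weibull shape < 1 has no mgf for t > 0
        with pytest.raises(ArithmeticError):
            frlx_mgf(1.0, frlw_params, BASE)


class TestResidualLife:
    def test_zero_offset_is_one(self, frlw_params):
        assert residual_life_sf(ResidualLifeQuery(t=1.0, x=0.0), frlw_params,
                                BASE) == pytest.approx(1.0)

    def test_decreasing_in_offset(self, frlw_params):
        xs = np.linspace(0.0, 5.0, 40)
        vals = [residual_life_sf(2.0, frlw_params, BASE, x=float(x)) for x in xs]
        assert np.all(np.diff(vals) <= 0)

    def test_matches_direct_survival_ratio(self, frlw_params):
        for t, x in [(0.5, 1.0), (2.0, 0.3), (4.0, 2.5)]:
            direct = (1.0 - frlx_cdf(x + t, frlw_params, BASE)) / (
                1.0 - frlx_cdf(t, frlw_params, BASE))
            assert residual_life_sf(t, frlw_params, BASE, x=x) == pytest.approx(
                direct, abs=1e-12)

    def test_reverse_ratio(self, frlw_params):
        val = reverse_residual_life_sf(1.0, frlw_params, BASE, x=3.0)
        direct = frlx_sf(2.0, frlw_params, BASE) / frlx_sf(1.0, frlw_params, BASE)
        assert val == pytest.approx(direct, abs=1e-12)

    def test_negative_elapsed_time_rejected(self, frlw_params):
        with pytest.raises(ValueError):
            residual_life_sf(-1.0, frlw_params, BASE, x=1.0)


class TestCharacterization:
    def test_closed_forms_at_lower_support(self, frlw_params):
        """Near the support start the two truncated moments take their closed forms."""
        s = frlw_params.sigma
        x = 1e-9
        res = characterization_check(x, frlw_params, BASE)
        L = math.log1p(s)
        # With F(x) ~ 0 and S_G(x) ~ 1: E[q1|X>=x] -> sigma/L, E[q2|X>=x] -> sigma/(2L)
        assert res.rhs == pytest.approx(0.5 * s / L, rel=1e-6)
        assert res.lhs == pytest.approx(0.5 * s / L, rel=1e-6)

    def test_identity_at_median(self, frlw_params):
        x = float(frlx_quantile(0.5, frlw_params, BASE))
        res = characterization_check(x, frlw_params, BASE)
        assert abs(res.gap) < 1e-6

    def test_identity_at_random_points_random_params(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            params = FRLXParams(
                sigma=float(rng.uniform(0.2, 4.0)),
                xi=(float(rng.uniform(0.5, 2.5)), float(rng.uniform(0.2, 2.0))),
            )
            x = float(frlx_quantile(float(rng.uniform(0.05, 0.9)), params, BASE))
            res = characterization_check(x, params, BASE)
            assert abs(res.gap) < 1e-6

    def test_wrong_eta_detected(self, frlw_params):
        x = float(frlx_quantile(0.5, frlw_params, BASE))
        res = characterization_check(x, frlw_params, BASE, eta_fn=lambda _: 0.5)
        assert abs(res.gap) > 1e-3

    def test_exhausted_survival_rejected(self, frlw_params):
        with pytest.raises(ValueError):
            characterization_check(1e8, FRLXParams(1.3, (2.0, 1.0)), BASE)


class TestBaselineContract:
    def test_weibull_baseline_invariants(self, base):
        xi = (1.7, 0.6)
        x = np.linspace(0.01, 6, 200)  # interior points: baseline tail not exhausted
        F = base.cdf(x, xi)
        assert np.all(np.diff(F) >= 0)
        assert base.cdf(0.0, xi) == 0.0
        np.testing.assert_allclose(base.quantile(F, xi), x, rtol=1e-9)
        total = integrate.quad(lambda t: float(base.pdf(t, xi)), 0, np.inf)[0]
        assert total == pytest.approx(1.0, abs=1e-8)
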