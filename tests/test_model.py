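"""Unit tests for the generative model building blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from srbmix.model import (
    AR1Params,
    HalfNormal,
    Hyperparams,
    ParameterError,
    RegionLatent,
    TrapezoidParams,
    TruncatedNormal,
    ar1_logpdf,
    expected_srb,
    joint_logpost,
    observation_loglik,
    trapezoid_alpha,
    trapezoid_profile,
)

TRAP = TrapezoidParams(gamma=2001, lambda1=12, lambda2=4, lambda3=18, xi=0.08)


class TestTrapezoid:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (1995, 0.0),        # before the start year
            (2001, 0.0),        # exactly at the start
            (2007, 0.04),       # midpoint of the rise
            (2013, 0.08),       # plateau onset
            (2017, 0.08),       # plateau end
            (2026, 0.04),       # decline: interpolate (2017, 0.08) -> (2035, 0)
            (2035, 0.0),        # return to normalcy
            (2050, 0.0),        # long after
        ],
    )
    def test_piecewise_values(self, t, expected):
        assert trapezoid_alpha(t, TRAP) == pytest.approx(expected, abs=1e-12)

    def test_decline_matches_linear_interpolation(self):
        # Independent check of the decline segment: straight line between
        # the plateau end (2017, xi) and the end year (2035, 0).
        for t in np.linspace(2017, 2035, 37):
            expected = np.interp(t, [2017, 2035], [0.08, 0.0])
            assert trapezoid_alpha(float(t), TRAP) == pytest.approx(expected, abs=1e-12)

    def test_continuity_and_nonnegativity(self):
        grid = np.linspace(1990, 2045, 20001)
        vals = trapezoid_alpha(grid, TRAP)
        assert np.all(vals >= 0)
        assert np.max(np.abs(np.diff(vals))) < 0.08 / 12 * (grid[1] - grid[0]) * 1.01

    def test_area_equals_closed_form(self):
        grid = np.linspace(1995, 2040, 200001)
        area = np.trapezoid(trapezoid_alpha(grid, TRAP), grid)
        closed = TRAP.xi * (TRAP.lambda1 / 2 + TRAP.lambda2 + TRAP.lambda3 / 2)
        assert area == pytest.approx(closed, rel=1e-6)

    @given(
        gamma=st.floats(1980, 2020),
        l1=st.floats(1.0, 25.0),
        l2=st.floats(0.0, 15.0),
        l3=st.floats(1.0, 30.0),
        xi=st.floats(0.0, 0.2),
    )
    @settings(max_examples=200, deadline=None)
    def test_support_and_maximum(self, gamma, l1, l2, l3, xi):
        p = TrapezoidParams(gamma, l1, l2, l3, xi)
        years = np.linspace(gamma - 10, p.end + 10, 801)
        vals = trapezoid_alpha(years, p)
        assert np.all(vals >= 0)
        assert np.all(vals[years <= gamma] == 0)
        assert np.all(vals[years >= p.end] == 0)
        assert np.max(vals) <= xi + 1e-12
        mid = gamma + l1 + l2 / 2
        assert trapezoid_alpha(mid, p) == pytest.approx(xi, abs=1e-9)

    @pytest.mark.parametrize("bad", [dict(lambda1=0), dict(lambda1=-2), dict(lambda3=0), dict(lambda2=-1), dict(xi=-0.01)])
    def test_invalid_parameters_raise(self, bad):
        kwargs = dict(gamma=2001, lambda1=12, lambda2=4, lambda3=18, xi=0.08)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            TrapezoidParams(**kwargs)

    def test_vectorized_profile_matches_scalar(self):
        years = np.arange(1990.0, 2040.0)
        gammas = np.array([1998.0, 2005.0])
        out = trapezoid_profile(years, gammas, [10.0, 12.0], [3.0, 4.0], [15.0, 18.0], [0.05, 0.08])
        assert out.shape == (2, len(years))
        p1 = TrapezoidParams(2005.0, 12.0, 4.0, 18.0, 0.08)
        np.testing.assert_allclose(out[1], trapezoid_alpha(years, p1))


class TestAR1:
    def test_logpdf_at_zero_closed_form(self):
        params = AR1Params(rho=0.5, sigma_eps=0.01)
        var0 = 0.0001 / 0.75
        expected = stats.norm.logpdf(0, 0, math.sqrt(var0)) + 2 * stats.norm.logpdf(0, 0, 0.01)
        assert ar1_logpdf(np.zeros(3), params) == pytest.approx(expected, rel=1e-12)

    def test_rho_zero_factorizes_to_iid(self):
        rng = np.random.default_rng(7)
        phi = rng.normal(0, 0.02, size=25)
        params = AR1Params(rho=1e-15, sigma_eps=0.015)
        iid = stats.norm.logpdf(phi, 0, 0.015).sum()
        assert ar1_logpdf(phi, params) == pytest.approx(iid, abs=1e-10)

    def test_matches_dense_covariance_oracle(self):
        # Oracle: multivariate normal with the analytic AR(1) covariance
        # sigma^2 * rho^|i-j| / (1 - rho^2).
        rng = np.random.default_rng(11)
        phi = rng.normal(0, 0.05, size=50)
        rho, sigma = 0.73, 0.02
        lag = np.abs(np.subtract.outer(np.arange(50), np.arange(50)))
        cov = sigma**2 * rho**lag / (1 - rho**2)
        oracle = stats.multivariate_normal(mean=np.zeros(50), cov=cov).logpdf(phi)
        assert ar1_logpdf(phi, AR1Params(rho, sigma)) == pytest.approx(oracle, abs=1e-8)

    def test_rows_are_independent_paths(self):
        rng = np.random.default_rng(3)
        phi = rng.normal(0, 0.01, size=(4, 30))
        params = AR1Params(0.4, 0.01)
        rows = ar1_logpdf(phi, params)
        assert rows.shape == (4,)
        for i in range(4):
            assert rows[i] == pytest.approx(ar1_logpdf(phi[i], params), rel=1e-12)

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.3])
    def test_nonstationary_rho_raises(self, rho):
        with pytest.raises(ParameterError):
            AR1Params(rho=rho, sigma_eps=0.01)


def _latent(phi_val, delta, trap=TRAP, years=None):
    years = np.arange(1995, 2040) if years is None else years
    return RegionLatent(
        region="RRD",
        years=years,
        phi=np.full(len(years), phi_val),
        delta=delta,
        pi=0.5,
        trapezoid=trap,
    )


class TestExpectedSRB:
    def test_baseline_identity(self):
        assert expected_srb(_latent(0.0, 0), 1.063, 2013) == pytest.approx(1.063)

    def test_peak_magnitude(self):
        trap = TrapezoidParams(2001, 12, 4, 18, 0.083)
        assert expected_srb(_latent(0.0, 1, trap), 1.063, 2013) == pytest.approx(1.146)

    def test_additive_composition(self):
        trap = TrapezoidParams(2001, 12, 4, 18, 0.05)
        lat = _latent(math.log(1.01), 1, trap)
        assert expected_srb(lat, 1.063, 2013) == pytest.approx(1.063 * 1.01 + 0.05)

    def test_year_outside_grid_raises(self):
        with pytest.raises(ParameterError):
            expected_srb(_latent(0.0, 0), 1.063, 2055)

    def test_detector_off_removes_imbalance(self):
        years = np.arange(1995, 2040)
        on = expected_srb(_latent(0.0, 1), 1.063, years)
        off = expected_srb(_latent(0.0, 0), 1.063, years)
        np.testing.assert_allclose(off, 1.063)
        assert np.all(on >= off)


class TestObservationLoglik:
    def test_mode_closed_form(self):
        got = observation_loglik(math.log(1.1), 0.02, 1.1, 0.0)
        assert got == pytest.approx(stats.norm.logpdf(0.0, 0.0, 0.02), rel=1e-12)

    def test_doubling_sd_costs_log2_at_mode(self):
        a = observation_loglik(math.log(1.1), 0.02, 1.1, 0.0)
        b = observation_loglik(math.log(1.1), 0.04, 1.1, 0.0)
        assert a - b == pytest.approx(math.log(2), rel=1e-12)

    def test_nonsampling_variance_adds_in_quadrature(self):
        direct = observation_loglik(0.05, 0.03, 1.1, 0.04)
        assert direct == pytest.approx(
            stats.norm.logpdf(0.05, math.log(1.1), math.sqrt(0.03**2 + 0.04**2)),
            rel=1e-12,
        )

    def test_sum_matches_pointwise_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.06, 0.03, size=10)
        se = rng.uniform(0.01, 0.05, size=10)
        srb = rng.uniform(1.0, 1.2, size=10)
        total = observation_loglik(y, se, srb, 0.01).sum()
        naive = sum(
            stats.norm.logpdf(yi, math.log(si), math.sqrt(sei**2 + 0.01**2))
            for yi, sei, si in zip(y, se, srb)
        )
        assert total == pytest.approx(naive, abs=1e-10)

    def test_invalid_expected_srb_raises(self):
        with pytest.raises(ParameterError):
            observation_loglik(0.05, 0.02, -1.0)


class TestJointLogpost:
    def _setup(self):
        import pandas as pd

        years = np.arange(2000, 2005)
        rng = np.random.default_rng(2)
        trap = TrapezoidParams(2001.0, 2.0, 1.0, 2.0, 0.05)
        lat = RegionLatent("RRD", years, rng.normal(0, 0.01, 5), 1, 0.6, trap)
        obs = pd.DataFrame(
            {
                "region": "RRD",
                "source_type": "census",
                "reference_year": [2001.0, 2002.0, 2004.0],
                "log_srb": [0.06, 0.10, 0.09],
                "sampling_se": [0.02, 0.03, 0.01],
            }
        )
        return lat, obs

    def test_matches_term_by_term_assembly(self):
        lat, obs = self._setup()
        hypers = Hyperparams()
        ar1 = AR1Params(0.5, 0.01)
        sigma_ns = {"census": 0.005}
        got = joint_logpost([lat], hypers, obs, ar1, sigma_ns)

        # Independent assembly of every term.
        expected = 0.0
        for _, row in obs.iterrows():
            srb = 1.063 * math.exp(lat.phi[int(row.reference_year) - 2000])
            srb += trapezoid_alpha(int(row.reference_year), lat.trapezoid)
            sd = math.sqrt(row.sampling_se**2 + 0.005**2)
            expected += stats.norm.logpdf(row.log_srb, math.log(srb), sd)
        expected += ar1_logpdf(lat.phi, ar1)
        expected += math.log(0.6)  # Bernoulli(delta=1 | pi)
        expected += stats.beta.logpdf(0.6, 1, 1)
        for name in ("gamma", "lambda1", "lambda2", "lambda3", "xi"):
            prior = getattr(hypers, name)
            expected += prior.logpdf(getattr(lat.trapezoid, name))
        expected += stats.halfnorm(scale=0.02).logpdf(0.01)
        expected += stats.halfnorm(scale=0.02).logpdf(0.005)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_empty_observations_gives_prior_only(self):
        import pandas as pd

        lat, obs = self._setup()
        hypers = Hyperparams()
        ar1 = AR1Params(0.5, 0.01)
        with_data = joint_logpost([lat], hypers, obs, ar1)
        prior_only = joint_logpost([lat], hypers, obs.iloc[:0], ar1)
        lik = sum(
            observation_loglik(
                row.log_srb, row.sampling_se, expected_srb(lat, 1.063, int(row.reference_year))
            )
            for row in obs.itertuples()
        )
        assert with_data - prior_only == pytest.approx(lik, abs=1e-9)

    def test_detector_off_makes_likelihood_invariant_to_trapezoid(self):
        lat, obs = self._setup()
        lat.delta = 0
        hypers = Hyperparams()
        ar1 = AR1Params(0.5, 0.01)
        base = joint_logpost([lat], hypers, obs, ar1)
        import dataclasses

        lat2 = RegionLatent(
            lat.region, lat.years, lat.phi, 0, lat.pi,
            dataclasses.replace(lat.trapezoid, xi=0.12),
        )
        moved = joint_logpost([lat2], hypers, obs, ar1)
        prior_diff = hypers.xi.logpdf(0.12) - hypers.xi.logpdf(lat.trapezoid.xi)
        assert moved - base == pytest.approx(prior_diff, abs=1e-9)

    def test_invariant_to_observation_order(self):
        lat, obs = self._setup()
        hypers = Hyperparams()
        ar1 = AR1Params(0.5, 0.01)
        shuffled = obs.sample(frac=1.0, random_state=4)
        assert joint_logpost([lat], hypers, obs, ar1) == pytest.approx(
            joint_logpost([lat], hypers, shuffled, ar1), rel=1e-12
        )


class TestPriors:
    def test_truncated_normal_support(self):
        p = TruncatedNormal(2001, 5, 1980, 2030)
        assert np.isneginf(p.logpdf_unnorm(1970))
        assert p.logpdf_unnorm(2001) == 0.0
        rng = np.random.default_rng(0)
        draws = p.rvs(rng, size=500)
        assert np.all((draws >= 1980) & (draws <= 2030))

    def test_half_normal_excludes_negative(self):
        h = HalfNormal(0.02)
        assert np.isneginf(h.logpdf_unnorm(-0.001))
        rng = np.random.default_rng(0)
        assert np.all(h.rvs(rng, size=100) >= 0)
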