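"""Seasonal Poisson-AR arrival model: mean, fitting, selection, simulation."""

import numpy as np
import pytest

from censuscast.arrivals import (
    HarmonicSpec,
    conditional_mean,
    estimate_frequency,
    fit_par,
    sample_arrival_params,
    select_order_bic,
    simulate_arrivals,
)
from censuscast._glm import poisson_loglik


def flat(T):
    return HarmonicSpec(0, (), T)


def simulate_par(beta0, ar, T, rng, harmonic=None):
    """Independent tiny simulator of the arrival law for recovery tests."""
    p = len(ar)
    lags = [np.exp(beta0)] * p
    out = []
    for day in range(T):
        eta = beta0 + sum(b * l for b, l in zip(ar, lags))
        if harmonic is not None:
            eta += float(harmonic.basis(day + 1)[0, 0])  # amplitude folded in
        a = rng.poisson(np.exp(eta))
        out.append(a)
        if p:
            lags = [a] + lags[:-1]
    return np.array(out)


class TestConditionalMean:
    def test_intercept_only(self):
        fit_params = np.array([np.log(3.0)])
        for t in (1, 50, 400):
            assert conditional_mean(fit_params, [], t, flat(100), 0) == pytest.approx(3.0)

    def test_single_lag(self):
        mu = conditional_mean(np.array([0.0, 0.1]), [5.0], 10, flat(100), 1)
        assert mu == pytest.approx(np.exp(0.5))

    def test_cos_term_at_phase_zero(self):
        # cos(2*pi*T*1/T) = cos(2*pi) = 1 at t = T
        harm = HarmonicSpec(1, (1.0,), 100)
        mu = conditional_mean(np.array([0.0, 1.0, 0.0]), [], 100, harm, 0)
        assert mu == pytest.approx(np.e)

    def test_wrong_lag_count(self):
        with pytest.raises(ValueError, match="lagged"):
            conditional_mean(np.array([0.0, 0.1]), [1.0, 2.0], 5, flat(100), 1)


class TestFitPar:
    def test_intercept_only_is_log_mean(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(4.0, size=200)
        fit = fit_par(y, 0)
        assert fit.intercept == pytest.approx(np.log(y.mean()), abs=1e-8)

    def test_loglik_matches_brute_force(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(3.0, size=50)
        fit = fit_par(y, 1)
        # brute-force conditional likelihood at the returned parameters
        import math

        ll = 0.0
        for t in range(2, 51):
            mu = conditional_mean(fit, [float(y[t - 2])], t)
            a = int(y[t - 1])
            ll += a * np.log(mu) - mu - math.log(math.factorial(a))
        assert fit.log_lik == pytest.approx(ll, rel=1e-9)

    def test_matches_statsmodels_glm(self):
        """Generic log-linear Poisson regression oracle on the same design."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        harm = HarmonicSpec(1, (2.0,), 300)
        y = simulate_par(1.0, (0.05,), 300, rng)
        fit = fit_par(y, 1, harm)
        t = np.arange(2, 301)
        X = np.column_stack(
            [np.ones(len(t)), y[t - 2], harm.basis(t)]
        )
        sm_fit = sm.GLM(y[t - 1], X, family=sm.families.Poisson()).fit()
        ours = poisson_loglik(fit.params, X, y[t - 1].astype(float))
        theirs = poisson_loglik(np.asarray(sm_fit.params), X, y[t - 1].astype(float))
        assert abs(ours - theirs) <= 1e-6 * abs(theirs)
        np.testing.assert_allclose(fit.params, sm_fit.params, rtol=1e-5, atol=1e-6)

    def test_parameter_recovery_par1(self):
        rng = np.random.default_rng(3)
        y = simulate_par(1.0, (0.05,), 3000, rng)
        fit = fit_par(y, 1)
        se = np.sqrt(np.diag(fit.param_cov))
        assert abs(fit.intercept - 1.0) < 3 * se[0]
        assert abs(fit.ar_coefs[0] - 0.05) < 3 * se[1]

    def test_rejects_bad_series(self):
        with pytest.raises(ValueError):
            fit_par([1, -2, 3], 0)
        with pytest.raises(ValueError):
            fit_par([1.5, 2.0], 0)


class TestOrderSelection:
    def test_single_candidate(self):
        rng = np.random.default_rng(4)
        p, table = select_order_bic(rng.poisson(3, 200), 0)
        assert p == 0 and len(table) == 1

    def test_iid_series_selects_zero(self):
        rng = np.random.default_rng(5)
        chosen = [
            select_order_bic(rng.poisson(3.0, 500), 3)[0] for _ in range(20)
        ]
        assert np.mean([c == 0 for c in chosen]) > 0.7

    def test_loglik_monotone_in_order_on_common_window(self):
        rng = np.random.default_rng(6)
        y = simulate_par(1.0, (0.06, 0.04), 600, rng)
        lls = [fit_par(y, p, n_condition=4).log_lik for p in range(5)]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


class TestFrequency:
    def test_recovers_planted_cycle_count(self):
        rng = np.random.default_rng(7)
        T = 546
        t = np.arange(1, T + 1)
        mu = np.exp(1.0 + 0.4 * np.cos(2 * np.pi * t * 3 / T))
        y = rng.poisson(mu)
        omega, acf = estimate_frequency(y, range(1, 9))
        assert omega == 3
        assert acf[0] == pytest.approx(1.0)

    def test_constant_series_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_frequency(np.full(100, 5), [1, 2])

    def test_single_candidate(self):
        rng = np.random.default_rng(8)
        omega, _ = estimate_frequency(rng.poisson(3, 120), [1])
        assert omega == 1


class TestParameterSampling:
    def test_zero_covariance_returns_estimate(self, par_fit):
        import dataclasses

        degen = dataclasses.replace(
            par_fit, param_cov=np.zeros_like(par_fit.param_cov)
        )
        draw = sample_arrival_params(degen, np.random.default_rng(0))
        np.testing.assert_array_equal(draw, par_fit.params)

    def test_monte_carlo_variance(self):
        from censuscast.arrivals import PARFit

        fit = PARFit(
            order=0, intercept=1.0, ar_coefs=(), cos_coefs=(), sin_coefs=(),
            param_cov=np.array([[0.25]]), log_lik=0.0, bic=0.0,
            harmonic=HarmonicSpec(0, (), 100), n_effective=100,
        )
        rng = np.random.default_rng(9)
        draws = np.array([sample_arrival_params(fit, rng)[0] for _ in range(10_000)])
        assert abs(draws.var() - 0.25) < 0.025
        assert abs(draws.mean() - 1.0) < 0.02

    def test_fixed_seed_reproducible(self, par_fit):
        a = sample_arrival_params(par_fit, np.random.default_rng(11))
        b = sample_arrival_params(par_fit, np.random.default_rng(11))
        np.testing.assert_array_equal(a, b)


class TestSimulateArrivals:
    def test_mean_matches_closed_form(self):
        from censuscast.arrivals import PARFit

        fit = PARFit(
            order=0, intercept=np.log(2.5), ar_coefs=(), cos_coefs=(),
            sin_coefs=(), param_cov=np.zeros((1, 1)), log_lik=0.0, bic=0.0,
            harmonic=HarmonicSpec(0, (), 100), n_effective=100,
        )
        rng = np.random.default_rng(12)
        draws = np.array(
            [simulate_arrivals(fit, [2, 3], 1, rng)[0] for _ in range(10_000)]
        )
        assert abs(draws.mean() - 2.5) < 3 * np.sqrt(2.5 / 10_000) + 0.05

    def test_degenerate_zero_mean(self):
        from censuscast.arrivals import PARFit

        fit = PARFit(
            order=0, intercept=-60.0, ar_coefs=(), cos_coefs=(), sin_coefs=(),
            param_cov=np.zeros((1, 1)), log_lik=0.0, bic=0.0,
            harmonic=HarmonicSpec(0, (), 100), n_effective=100,
        )
        out = simulate_arrivals(fit, [1], 5, np.random.default_rng(0))
        assert (out == 0).all()

    def test_history_shorter_than_order(self, par_fit):
        with pytest.raises(ValueError, match="shorter"):
            simulate_arrivals(par_fit, [], 3, np.random.default_rng(0))
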