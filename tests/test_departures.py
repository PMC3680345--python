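"""Departure labels, stratified logistic fits, and departure sampling."""

import numpy as np
import pytest
from scipy.special import expit

from censuscast.data_model import CensusState, PatientRecord
from censuscast.departures import (
    DepartureModel,
    DepartureModelSet,
    StratumSpec,
    build_training_table,
    departure_prob,
    fit_departure_models,
    make_label,
    sample_departures_in_census,
    sample_pseudo_subjects,
)
from censuscast.synthetic import GeneratorConfig, generate_unit_history, true_departure_prob


def rec(pid, admit=0, los=None, censored_at=None, **kw):
    kw.setdefault("bweight", 3000.0)
    kw.setdefault("gestage", 38.0)
    return PatientRecord(pid, admit, los=los, censored_at=censored_at, **kw)


class TestLabels:
    def test_departure_within_horizon(self):
        assert make_label(rec("a", los=3), 1, 2).y == 1  # LOS 3 <= k+s = 3

    def test_undefined_when_not_at_risk(self):
        assert make_label(rec("a", los=3), 2, 3).y is None  # LOS <= s

    def test_stay_exceeds_horizon(self):
        assert make_label(rec("a", los=5), 1, 0).y == 0

    def test_censoring_determines_zero(self):
        # still present after 6 days => LOS > 6 >= k+s = 5 => Y = 0
        assert make_label(rec("a", censored_at=6), 2, 3).y == 0

    def test_censoring_leaves_label_open(self):
        assert make_label(rec("a", censored_at=4), 2, 3).y is None

    def test_cutoff_censors_known_stay(self):
        r = rec("a", admit=0, los=10)
        # by day 2 only LOS > 2 is known, short of k+s = 3: label open
        assert make_label(r, 2, 1, cutoff_day=2).y is None
        # by day 4 censoring proves LOS > 4 >= k+s: a determined zero
        assert make_label(r, 2, 1, cutoff_day=4).y == 0
        assert make_label(r, 2, 1, cutoff_day=20).y == 0

    def test_horizon_monotonicity(self):
        """Y^(k,s) = 1 implies Y^(k',s) = 1 for k' > k when both defined."""
        for los in range(1, 12):
            r = rec("a", los=los)
            for s in range(0, 12):
                ys = [make_label(r, k, s).y for k in range(1, 10)]
                defined = [y for y in ys if y is not None]
                assert defined == sorted(defined)  # 0s before 1s, monotone


class TestStratumSpec:
    def test_covariate_sets_follow_availability(self):
        spec = StratumSpec(10)
        assert spec.covariate_names(0) == ("bweight", "gestage")
        assert spec.covariate_names(1) == ("bweight", "gestage", "snapdol1", "main1")
        assert spec.covariate_names(3) == (
            "bweight", "gestage", "snapdol1", "main1", "snapdol3")
        assert spec.covariate_names(7)[-1] == "main7"
        assert spec.covariate_names(10) == spec.covariate_names(7)

    def test_stratum_mapping(self):
        spec = StratumSpec(10)
        assert spec.stratum_of(0) == 0
        assert spec.stratum_of(9) == 9
        assert spec.stratum_of(25) == 10


class TestTrainingTable:
    def test_single_patient_single_row(self):
        t = build_training_table([rec("a", los=2)], 1, 0, StratumSpec(10))
        assert t.n == 1 and t.y[0] == 0  # LOS 2 > k+s = 1

    def test_pooled_stratum_row_per_at_risk_day(self):
        long_stay = rec("a", los=12, snapdol1=5.0, main1=200.0, snapdol3=3.0,
                        main7=300.0)
        t = build_training_table([long_stay], 1, 10, StratumSpec(10))
        assert t.n == 2  # s = 10, 11; s = 12 not at risk (LOS <= s)
        assert sorted(t.s_values.tolist()) == [10, 11]

    def test_cutoff_before_outcomes(self):
        t = build_training_table(
            [rec("a", admit=5, los=9)], 3, 2, StratumSpec(10), cutoff_day=6
        )
        assert t.n == 0  # censored at c=1 < k+s: label open


class TestFitting:
    def test_coefficient_recovery_well_specified(self):
        """Large-n logistic-law recovery at the baseline stratum."""
        rng = np.random.default_rng(0)
        n = 6000
        ga = np.round(np.clip(34.6 + 4 * rng.standard_normal(n), 22, 42))
        b0, b1 = -2.0, 0.25
        pi = expit(b0 + b1 * (ga - 34.6))
        leaves = rng.random(n) < pi
        records = [
            rec(f"p{i}", los=(1 if leaves[i] else 50), gestage=float(ga[i]),
                bweight=3000.0 + 10 * float(rng.standard_normal()))
            for i in range(n)
        ]
        ms = fit_departure_models(records, [1], StratumSpec(1), ridge=1e-8)
        m = ms.models[(1, 0)]
        raw = m.raw_coef
        se = np.sqrt(np.diag(m.raw_cov))
        assert abs(raw[0] - (b0 - b1 * 34.6)) < 3 * se[0]
        assert abs(raw[2] - b1) < 3 * se[2]  # gestage slope

    def test_matches_unpenalized_logistic_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 800
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(-0.5 + 0.8 * x)).astype(float)
        from censuscast._glm import fit_logistic_ridge

        X = np.column_stack([np.ones(n), x])
        ours = fit_logistic_ridge(X, y, ridge=0.0)
        theirs = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.coef, theirs.params, rtol=1e-5, atol=1e-6)
        assert abs(ours.log_lik - theirs.llf) <= 1e-5 * abs(theirs.llf)

    def test_all_events_stratum_falls_back(self):
        records = [rec(f"p{i}", los=1, gestage=30.0 + i % 5) for i in range(40)]
        ms = fit_departure_models(records, [7], StratumSpec(1))
        m = ms.models[(7, 0)]  # every label is 1: separation
        assert m.fallback == "intercept_only"
        assert 0.9 < expit(m.coef[0]) < 1.0  # clamped below 1

    def test_sparse_stratum_pools_downward(self, history):
        ms = fit_departure_models(
            history.records, [1], StratumSpec(10), cutoff_day=12
        )
        flags = [m.fallback for m in ms.models.values()]
        assert any(f and f.startswith("pooled") for f in flags) or any(
            f == "intercept_only" for f in flags
        )


class TestDepartureProb:
    def model(self, coef, names=("bweight", "gestage")):
        d = len(coef)
        return DepartureModel(
            k=1, stratum=0, covariate_names=names,
            coef=np.asarray(coef, float), cov=np.eye(d),
            x_mean=np.zeros(d - 1), x_scale=np.ones(d - 1),
            n=10, n_events=5, ridge=0.0,
        )

    def test_null_coefficients(self):
        assert departure_prob(self.model([0.0, 0.0, 0.0]), [1.0, 2.0]) == 0.5

    def test_closed_form(self):
        m = self.model([np.log(3.0), 0.0, 0.0])
        assert departure_prob(m, [5.0, 5.0]) == pytest.approx(0.75)

    def test_symmetry(self):
        m = self.model([0.3, 0.5, -0.2])
        z = np.array([1.0, 2.0])
        mneg = self.model([-0.3, -0.5, 0.2])
        assert departure_prob(m, z) + departure_prob(mneg, z) == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="covariates"):
            departure_prob(self.model([0.0, 1.0, 1.0]), [1.0])


class TestSampling:
    def make_set(self, pi):
        """Intercept-only model set with departure probability pi."""
        from scipy.special import logit

        spec = StratumSpec(1)
        models = {}
        for st in spec.strata:
            models[(1, st)] = DepartureModel(
                k=1, stratum=st, covariate_names=(),
                coef=np.array([logit(np.clip(pi, 1e-12, 1 - 1e-12))]),
                cov=np.zeros((1, 1)), x_mean=np.empty(0), x_scale=np.empty(0),
                n=10, n_events=5, ridge=0.0,
            )
        return DepartureModelSet(models=models, spec=spec, horizons=(1,))

    def state(self, n):
        recs = [rec(f"p{i}", admit=0, censored_at=2) for i in range(n)]
        return CensusState(day=2, present=tuple((r, 2) for r in recs))

    def test_certain_departure_empties_census(self):
        draws, total = sample_departures_in_census(
            self.state(7), self.make_set(1.0 - 1e-15), 1, np.random.default_rng(0)
        )
        assert total == 7 == draws.sum()

    def test_empty_census(self):
        state = CensusState(day=0, present=())
        _, total = sample_departures_in_census(
            state, self.make_set(0.5), 1, np.random.default_rng(0)
        )
        assert total == 0

    def test_expected_departures_match_probability_sum(self, dep_models, origin_state):
        state, _ = origin_state
        small = CensusState(day=state.day, present=state.present[:5])
        rng = np.random.default_rng(2)
        totals = [
            sample_departures_in_census(small, dep_models, 3, rng)[1]
            for _ in range(10_000)
        ]
        # expectation oracle: sum of model probabilities over the census
        exp_total = 0.0
        for r, s in small.present:
            m = dep_models.model_for(3, s)
            z = [r.covariate(n) for n in m.covariate_names]
            exp_total += departure_prob(m, z)
        se = np.sqrt(exp_total)  # loose Poisson-binomial bound / sqrt(n)
        assert abs(np.mean(totals) - exp_total) < 4 * se / 100 + 0.02


class TestPseudoSubjects:
    def test_zero_draws(self):
        assert sample_pseudo_subjects([rec("a", los=2)], 0, np.random.default_rng(0)).shape == (0, 2)

    def test_degenerate_pool(self):
        out = sample_pseudo_subjects(
            [rec("a", los=2, bweight=1234.0, gestage=30.0)], 5,
            np.random.default_rng(0),
        )
        assert (out == [1234.0, 30.0]).all()

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError, match="pool"):
            sample_pseudo_subjects([], 3, np.random.default_rng(0))

    def test_bootstrap_mean(self, history):
        pool_mean = np.mean([r.bweight for r in history.records])
        out = sample_pseudo_subjects(
            history.records, 20_000, np.random.default_rng(3)
        )
        sd = np.std([r.bweight for r in history.records])
        assert abs(out[:, 0].mean() - pool_mean) < 3 * sd / np.sqrt(20_000)


def test_fitted_probability_tracks_true_conditional_law(history):
    """With every severity score observable (stratum >= 7), the fitted
    pi-hat^(k) at a central covariate profile approximates the true
    discrete-hazard probability P(LOS <= s+k | LOS > s, z)."""
    ms = fit_departure_models(history.records, [3], StratumSpec(10))
    z = {
        "bweight": 2400.0, "gestage": 34.0, "snapdol1": 8.0,
        "main1": 480.0, "snapdol3": 5.0, "main7": 650.0,
    }
    m = ms.models[(3, 7)]
    assert m.fallback is None
    zt = [z[n] for n in m.covariate_names]
    pi_hat = departure_prob(m, zt)
    pi_true = true_departure_prob(history.config, z, 3, 7)
    assert abs(pi_hat - pi_true) < 0.06
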