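"""Shared fixtures: one synthetic unit history at the default study scale,
plus fitted models and the full continuously-updating backtest, all
session-scoped so expensive objects are built once."""

from __future__ import annotations

import numpy as np
import pytest

from censuscast import (
    BacktestConfig,
    EnsembleConfig,
    GeneratorConfig,
    HarmonicSpec,
    StratumSpec,
    fit_departure_models,
    fit_par,
    generate_unit_history,
    run_backtest,
)
from censuscast.backtest import BacktestReport
from censuscast.data_model import build_census_state, censor_record


HISTORY_SEED = 1
BACKTEST_SEED = 1
SPLIT_DAY = 443          # leaves 100 fully scorable test origins of 550 days
N_TEST_DAYS = 100
ENSEMBLE_M = 200


@pytest.fixture(scope="session")
def history():
    """Default-calibration unit history (~550 days, ~1500 admissions)."""
    return generate_unit_history(GeneratorConfig(), seed=HISTORY_SEED)


@pytest.fixture(scope="session")
def small_history():
    return generate_unit_history(GeneratorConfig(n_days=300), seed=99)


@pytest.fixture(scope="session")
def par_fit(history):
    T = 400
    harmonic = HarmonicSpec(1, (history.config.arrival_frequency * T / history.config.n_days,), T)
    return fit_par(history.arrivals[:T], p=1, harmonic=harmonic)


@pytest.fixture(scope="session")
def dep_models(history):
    return fit_departure_models(
        history.records, range(1, 8), StratumSpec(10), cutoff_day=400
    )


@pytest.fixture(scope="session")
def origin_state(history):
    known = [
        r for r in (censor_record(rec, 400) for rec in history.records) if r
    ]
    return build_census_state(known, 400), known


@pytest.fixture(scope="session")
def forecast(par_fit, dep_models, origin_state, history):
    """A mid-history ensemble forecast (M=300) plus its origin state."""
    from censuscast import forecast_census

    state, known = origin_state
    cfg = EnsembleConfig(n_realizations=300, horizons=(1, 3, 5, 7), seed=3)
    return (
        forecast_census(
            state, par_fit, dep_models, known, cfg,
            history.arrivals[:401], t_origin=401,
        ),
        state,
    )


@pytest.fixture(scope="session")
def backtest_report(history) -> BacktestReport:
    """The continuously-updating evaluation at the study conditions: 100
    consecutive test origins, weekly refits, M=200 realizations, with the
    census-only comparator."""
    cfg = BacktestConfig(
        split_day=SPLIT_DAY,
        n_test_days=N_TEST_DAYS,
        refit_cadence=7,
        ensemble=EnsembleConfig(n_realizations=ENSEMBLE_M, seed=BACKTEST_SEED),
        comparator=True,
    )
    return run_backtest(history.records, history.arrivals, cfg)
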