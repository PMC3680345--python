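"""Continuously-updating (expanding-window) prospective evaluation.

From each forecast origin in the test window the models see only
information determinable by that day: the arrival series is truncated at
the origin, patient records are censored at the origin (unknown length of
stay becomes a lower bound; severity scores not yet collected are hidden),
and the census state is rebuilt from those censored records.  As the origin
advances the training window absorbs each elapsed test day.

Accuracy is summarised per horizon by MAPE — here the mean absolute
prediction error in patient counts, not a percentage — with a normal-
approximation 95% confidence interval, the empirical coverage of the 95%
prediction interval, and the distribution of interval widths.  A
census-only comparator applies the identical seasonal Poisson-AR machinery
directly to the daily census-count series, ignoring patient-level
information, and is scored through the same metric code path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .arrivals import (
    HarmonicSpec,
    PARFit,
    estimate_frequency,
    fit_par,
    select_order_bic,
    simulate_arrivals,
)
from ._glm import mvn_factor
from .data_model import PatientRecord, build_census_state, censor_record
from .departures import StratumSpec, fit_departure_models
from .ensemble import EnsembleConfig, forecast_census, summarize_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "BacktestConfig",
    "BacktestReport",
    "run_backtest",
    "mape",
    "interval_metrics",
    "census_only_comparator",
    "summarize_rows",
]


@dataclass(frozen=True)
class BacktestConfig:
    """Expanding-window backtest settings.

    ``refit_cadence`` is the number of days between model refits (1 = refit
    daily, as the continuously-updating procedure implies); between refits
    the last fitted models are reused but the census state and training
    labels still advance with the origin.  The autoregressive order and the
    seasonal frequency are selected once, at the first origin, and held
    fixed across refits.
    """

    split_day: int
    horizons: tuple[int, ...] = (1, 3, 5, 7)
    refit_cadence: int = 1
    n_test_days: Optional[int] = None
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    stratum_spec: StratumSpec = field(default_factory=StratumSpec)
    p_max: int = 3
    n_harmonics: int = 1
    freq_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    ridge: float = 1e-4
    min_rows: int = 10
    comparator: bool = False

    def __post_init__(self) -> None:
        if self.refit_cadence < 1:
            raise ValueError("refit_cadence must be >= 1")
        if self.split_day < 1:
            raise ValueError("split_day must leave a nonempty training window")


@dataclass
class BacktestReport:
    """Per-day forecasts and per-horizon metrics (plus comparator copies)."""

    per_day: pd.DataFrame      # origin, horizon, observed, point, lo, hi, ...
    summary: pd.DataFrame      # indexed by horizon
    comparator_per_day: Optional[pd.DataFrame] = None
    comparator_summary: Optional[pd.DataFrame] = None


def mape(
    observed: Sequence[float], forecast: Sequence[float]
) -> tuple[float, tuple[float, float]]:
    """Mean absolute prediction error (in counts) with a 95% CI from the
    normal approximation on the absolute errors."""
    obs = np.asarray(observed, float)
    fc = np.asarray(forecast, float)
    if obs.shape != fc.shape or obs.size == 0:
        raise ValueError("observed and forecast must be nonempty equal-length")
    err = np.abs(obs - fc)
    m = float(err.mean())
    se = float(err.std(ddof=1) / np.sqrt(len(err))) if len(err) > 1 else 0.0
    return m, (m - 1.96 * se, m + 1.96 * se)


def interval_metrics(per_day: pd.DataFrame) -> tuple[float, np.ndarray]:
    """Empirical coverage and per-day interval widths from a per-day table
    with columns observed, lo, hi."""
    if len(per_day) == 0:
        raise ValueError("empty per-day table")
    if (per_day["lo"] > per_day["hi"]).any():
        raise ValueError("intervals must satisfy lo <= hi")
    covered = (per_day["lo"] <= per_day["observed"]) & (
        per_day["observed"] <= per_day["hi"]
    )
    widths = (per_day["hi"] - per_day["lo"]).to_numpy(float)
    return float(covered.mean()), widths


def summarize_rows(per_day: pd.DataFrame) -> pd.DataFrame:
    """Per-horizon metric table from a per-day forecast table."""
    out = []
    for k, grp in per_day.groupby("horizon"):
        m, (lo_ci, hi_ci) = mape(grp["observed"], grp["point"])
        coverage, widths = interval_metrics(grp)
        out.append(
            {
                "horizon": int(k),
                "n": len(grp),
                "mape": m,
                "mape_ci_low": lo_ci,
                "mape_ci_high": hi_ci,
                "coverage": coverage,
                "mean_width": float(widths.mean()),
                "median_width": float(np.median(widths)),
            }
        )
    return pd.DataFrame(out).set_index("horizon")


def observed_census_series(
    records: Sequence[PatientRecord], n_days: int
) -> np.ndarray:
    """End-of-day census C(t) for t = 0..n_days-1 tallied from records."""
    census = np.zeros(n_days, dtype=int)
    for r in records:
        a = r.admit_day
        last = min(a + r.max_stay_day, n_days - 1)
        if last >= 0 and a < n_days:
            census[max(a, 0) : last + 1] += 1
    return census


def _origin_seed(base: int, origin: int) -> int:
    # deterministic per-origin ensemble seed, kept within int32 range
    return int((base * 1_000_003 + origin * 7919 + 17) % (2**31 - 1))


def run_backtest(
    records: Sequence[PatientRecord],
    arrival_series: Sequence[int],
    config: BacktestConfig,
) -> BacktestReport:
    """Expanding-window backtest of the ensemble forecaster.

    For each test origin t the training set is everything determinable by
    day t; models are refit every ``refit_cadence`` days; forecasts at each
    horizon k are scored against the observed census at t+k (origins whose
    t+k falls beyond the data are skipped for that horizon).
    """
    series = np.asarray(arrival_series, int)
    n_days = len(series)
    split = config.split_day
    horizons = tuple(sorted(set(config.horizons)))
    k_max = horizons[-1]
    if not 0 < split < n_days:
        raise ValueError("split must leave nonempty train and test windows")
    n_test = config.n_test_days
    last_origin = n_days - 2  # need at least one scorable horizon (k=1)
    origins = range(split, last_origin + 1)
    if n_test is not None:
        origins = range(split, min(split + n_test, last_origin + 1))
    if len(origins) == 0:
        raise ValueError("no usable forecast origins in the test window")

    census_obs = observed_census_series(records, n_days)
    par_fit: Optional[PARFit] = None
    dep_models = None
    p_order: Optional[int] = None
    harmonic: Optional[HarmonicSpec] = None
    rows = []
    for t in origins:
        if par_fit is None or (t - split) % config.refit_cadence == 0:
            train = series[: t + 1]
            if harmonic is None:
                if config.n_harmonics > 0:
                    omega, _ = estimate_frequency(train, config.freq_candidates)
                    harmonic = HarmonicSpec(
                        config.n_harmonics,
                        tuple(
                            float(omega * (h + 1))
                            for h in range(config.n_harmonics)
                        ),
                        len(train),
                    )
                else:
                    harmonic = HarmonicSpec(0, (), len(train))
                p_order, _ = select_order_bic(train, config.p_max, harmonic)
                logger.info("selected omega=%s, p=%d at first origin",
                            harmonic.frequencies, p_order)
            par_fit = fit_par(train, p_order, harmonic)
            dep_models = fit_departure_models(
                records,
                range(1, k_max + 1),
                config.stratum_spec,
                cutoff_day=t,
                ridge=config.ridge,
                min_rows=config.min_rows,
            )
        known = [
            r for r in (censor_record(rec, t) for rec in records) if r is not None
        ]
        state = build_census_state(known, t)
        ens = replace(config.ensemble, horizons=horizons,
                      seed=_origin_seed(config.ensemble.seed, t))
        fc = forecast_census(
            state, par_fit, dep_models, known, ens, series[: t + 1], t_origin=t + 1
        )
        for k in horizons:
            if t + k >= n_days:
                continue
            rows.append(
                {
                    "origin": t,
                    "horizon": k,
                    "observed": int(census_obs[t + k]),
                    "point": fc.point[k],
                    "lo": fc.lo[k],
                    "hi": fc.hi[k],
                }
            )
    per_day = pd.DataFrame(rows)
    summary = summarize_rows(per_day)
    report = BacktestReport(per_day=per_day, summary=summary)
    if config.comparator:
        cmp_day = census_only_comparator(census_obs, config)
        report.comparator_per_day = cmp_day
        report.comparator_summary = summarize_rows(cmp_day)
    return report


def census_only_comparator(
    census_series: Sequence[int],
    config: BacktestConfig,
) -> pd.DataFrame:
    """Benchmark that models the daily census-count series itself with the
    seasonal Poisson-AR machinery, ignoring patient-level information.

    Frequency and order are selected on the training census counts; each
    origin's forecast is an ensemble of parameter draws followed by
    sequential Poisson simulation of the census k steps ahead, summarised
    exactly like the primary model.  Returns the per-day forecast table.
    """
    series = np.asarray(census_series, int)
    n_days = len(series)
    split = config.split_day
    horizons = tuple(sorted(set(config.horizons)))
    k_max = horizons[-1]
    last_origin = n_days - 2
    origins = range(split, last_origin + 1)
    if config.n_test_days is not None:
        origins = range(split, min(split + config.n_test_days, last_origin + 1))

    harmonic: Optional[HarmonicSpec] = None
    p_order: Optional[int] = None
    fit: Optional[PARFit] = None
    rows = []
    for t in origins:
        if fit is None or (t - split) % config.refit_cadence == 0:
            train = series[: t + 1]
            if harmonic is None:
                if config.n_harmonics > 0:
                    omega, _ = estimate_frequency(train, config.freq_candidates)
                    harmonic = HarmonicSpec(
                        config.n_harmonics,
                        tuple(
                            float(omega * (h + 1))
                            for h in range(config.n_harmonics)
                        ),
                        len(train),
                    )
                else:
                    harmonic = HarmonicSpec(0, (), len(train))
                p_order, _ = select_order_bic(train, config.p_max, harmonic)

            fit = fit_par(train, p_order, harmonic)
        M = config.ensemble.n_realizations
        children = np.random.SeedSequence(
            _origin_seed(config.ensemble.seed, t)
        ).spawn(M)
        factor = mvn_factor(fit.param_cov)
        reals = np.zeros((M, k_max), dtype=int)
        for r in range(M):
            rng = np.random.default_rng(children[r])
            lam = fit.params + factor @ rng.standard_normal(len(fit.params))
            reals[r] = simulate_arrivals(
                fit, series[: t + 1], k_max, rng, params=lam, t_origin=t + 1
            )
        for k in horizons:
            if t + k >= n_days:
                continue
            pt, lo, hi = summarize_ensemble(
                reals[:, k - 1], config.ensemble.point, config.ensemble.quantiles
            )
            rows.append(
                {
                    "origin": t,
                    "horizon": k,
                    "observed": int(series[t + k]),
                    "point": pt,
                    "lo": lo,
                    "hi": hi,
                }
            )
    return pd.DataFrame(rows)


def plot_backtest(report: BacktestReport, out_path: Optional[str] = None):
    """Observed-vs-predicted panels with 95% interval bands, one per horizon
    (the per-day view of forecast accuracy)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    horizons = sorted(report.per_day["horizon"].unique())
    fig, axes = plt.subplots(
        len(horizons), 1, figsize=(9, 2.6 * len(horizons)), sharex=True
    )
    axes = np.atleast_1d(axes)
    for ax, k in zip(axes, horizons):
        grp = report.per_day[report.per_day["horizon"] == k]
        ax.fill_between(grp["origin"], grp["lo"], grp["hi"], alpha=0.25,
                        label="95% PI")
        ax.plot(grp["origin"], grp["observed"], "k-", lw=1, label="observed")
        ax.plot(grp["origin"], grp["point"], "C1-", lw=1, label="forecast")
        ax.set_ylabel(f"census (k={k})")
    axes[0].legend(loc="upper right", fontsize=8)
    axes[-1].set_xlabel("forecast origin day")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
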