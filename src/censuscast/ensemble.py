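"""Stochastic ensemble census forecasts with percentile prediction intervals.

Each of M realizations propagates every source of randomness the method
recognises:

1. arrival-model parameters drawn from MVN(lam_hat, V_lam) and departure
   coefficients from MVN(beta_hat^(k,s), V_beta^(k,s)) per (horizon,
   stratum) — estimation uncertainty;
2. arrivals over the horizon sampled sequentially from the Poisson
   conditional means (sampled counts feeding later lags);
3. a Bernoulli within-k departure indicator per current-census patient from
   its stratum's model;
4. pseudo-subjects — baseline covariates resampled with replacement from
   training admissions — standing in for patients arriving on intermediate
   days t+1..t+k-1, each drawing a departure-by-t+k indicator from the
   (k-j, s=0) model (day-t+k arrivals cannot have departed by t+k);
5. the census identity C^(r)(t+k) = C(t) + sum A^(r) - cumulative D^(r).

Cumulative departures by t+k are computed directly from the within-k
indicators (one draw per at-risk individual), so no double counting across
days can occur; horizons are forecast independently, not chained.

The point forecast is the ensemble median (configurable) and the interval
the 2.5/97.5 empirical percentiles (numpy linear interpolation).  Every
realization r uses its own child stream of the master seed
(``SeedSequence(seed).spawn``), so enlarging M extends, never reshuffles,
the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from ._glm import mvn_factor
from .arrivals import PARFit, simulate_arrivals
from .data_model import CensusState, PatientRecord
from .departures import DepartureModelSet, sample_pseudo_subjects

__all__ = ["EnsembleConfig", "ForecastResult", "forecast_census", "summarize_ensemble"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble size, horizons, interval and summary settings."""

    n_realizations: int = 1000
    horizons: tuple[int, ...] = (1, 3, 5, 7)
    quantiles: tuple[float, float] = (0.025, 0.975)
    point: str = "median"  # or "mean"
    seed: int = 0
    couple_departures: bool = False  # shared uniform per patient across horizons

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("need at least one realization")
        lo, hi = self.quantiles
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("quantiles must satisfy 0 < lo < hi < 1")
        if self.point not in ("median", "mean"):
            raise ValueError("point summary must be 'median' or 'mean'")
        if any(k < 1 for k in self.horizons) or not self.horizons:
            raise ValueError("horizons must be integers >= 1")


@dataclass
class ForecastResult:
    """Ensemble forecast from one origin day."""

    origin: int
    horizons: tuple[int, ...]
    realizations: dict[int, np.ndarray]      # k -> (M,) census draws
    point: dict[int, float]
    lo: dict[int, float]
    hi: dict[int, float]
    arrivals: np.ndarray                     # (M, max horizon) sampled A
    departures: dict[int, np.ndarray]        # k -> (M,) cumulative departures
    seed: int
    census_at_origin: int


def summarize_ensemble(
    realizations: Sequence[float],
    point: str = "median",
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> tuple[float, float, float]:
    """Point summary and empirical percentile interval of an ensemble.

    Quantiles use numpy's default linear interpolation between order
    statistics.
    """
    arr = np.asarray(realizations, float)
    if arr.size == 0:
        raise ValueError("empty ensemble")
    pt = float(np.median(arr)) if point == "median" else float(np.mean(arr))
    lo, hi = (float(q) for q in np.quantile(arr, quantiles))
    return pt, lo, hi


def _stratum_designs(
    state: CensusState, model_set: DepartureModelSet, horizons: Sequence[int]
) -> dict[tuple[int, int], np.ndarray]:
    """Per (k, stratum): standardised design matrix (with intercept) of the
    census patients in that stratum, in stable patient order."""
    spec = model_set.spec
    groups: dict[int, list[PatientRecord]] = {}
    for rec, s in state.present:
        groups.setdefault(spec.stratum_of(s), []).append(rec)
    designs: dict[tuple[int, int], np.ndarray] = {}
    for k in horizons:
        for st, recs in sorted(groups.items()):
            model = model_set.models.get((k, st))
            if model is None:
                raise ValueError(
                    f"horizon {k} requested but no departure model fitted "
                    f"for stratum {st}"
                )
            if model.covariate_names:
                Z = np.empty((len(recs), len(model.covariate_names)))
                for i, rec in enumerate(recs):
                    for j, name in enumerate(model.covariate_names):
                        v = rec.covariate(name)
                        if v is None:
                            raise ValueError(
                                f"patient {rec.patient_id}: missing covariate "
                                f"{name!r} for (k={k}, stratum={st})"
                            )
                        Z[i, j] = v
                Zs = (Z - model.x_mean) / model.x_scale
                designs[(k, st)] = np.column_stack([np.ones(len(recs)), Zs])
            else:
                designs[(k, st)] = np.ones((len(recs), 1))
    return designs


def forecast_census(
    state: CensusState,
    par_fit: PARFit,
    dep_models: DepartureModelSet,
    training_records: Sequence[PatientRecord],
    config: EnsembleConfig,
    arrival_history: Sequence[float],
    *,
    t_origin: Optional[int] = None,
) -> ForecastResult:
    """The six-step ensemble procedure from origin day ``state.day``.

    ``arrival_history`` is the observed arrival series through the origin;
    ``t_origin`` (1-based index of its last day, default its length) anchors
    the harmonic phase of simulated arrivals.
    """
    horizons = tuple(sorted(set(config.horizons)))
    k_max = horizons[-1]
    needed = {1, *horizons, *range(1, k_max)}
    missing = [k for k in needed if k > dep_models.max_horizon]
    if missing:
        raise ValueError(
            f"horizons {missing} exceed the fitted departure horizons "
            f"(max {dep_models.max_horizon})"
        )
    M = config.n_realizations
    designs = _stratum_designs(state, dep_models, sorted(needed))
    census_keys = sorted({key for key in designs})
    pseudo_keys = sorted(
        (k - j, 0) for k in [k_max] for j in range(1, k_max)
    )  # models used by pseudo-subjects: horizons 1..k_max-1 at s=0
    block_keys = sorted(set(census_keys) | set(pseudo_keys))
    pool = _baseline_pool(training_records)
    par_factor = mvn_factor(par_fit.param_cov)
    lam_hat = par_fit.params

    children = np.random.SeedSequence(config.seed).spawn(M)
    arrivals_out = np.zeros((M, k_max), dtype=int)
    census_reals = {k: np.zeros(M, dtype=int) for k in horizons}
    dep_reals = {k: np.zeros(M, dtype=int) for k in horizons}
    c_t = state.census_count

    for r in range(M):
        rng = np.random.default_rng(children[r])
        lam = lam_hat + par_factor @ rng.standard_normal(len(lam_hat))
        a_r = simulate_arrivals(
            par_fit, arrival_history, k_max, rng, params=lam, t_origin=t_origin
        )
        arrivals_out[r] = a_r
        coefs = {
            key: dep_models.models[key].sample_coefs(rng) for key in block_keys
        }
        if config.couple_departures:
            # one uniform per current patient (by stratum group) and one
            # (baseline, uniform) pair per pseudo-subject, shared across k
            strata_present = sorted({st for (_, st) in census_keys})
            u_strata = {
                st: rng.random(designs[(sorted(needed)[0], st)].shape[0])
                for st in strata_present
            }
            pseudo_draws = []
            for j in range(1, k_max):
                nj = int(a_r[j - 1])
                zb = (
                    pool[rng.integers(0, len(pool), nj)]
                    if nj and len(pool)
                    else np.empty((0, 2))
                )
                if nj and not len(pool):
                    raise ValueError("empty training pool for pseudo-subjects")
                pseudo_draws.append((zb, rng.random(nj)))
        for k in horizons:
            d_total = 0
            for key in census_keys:
                if key[0] != k:
                    continue
                _, st = key
                coef = coefs[key]
                pi = expit(designs[key] @ coef)
                if config.couple_departures:
                    u = u_strata[st]
                else:
                    u = rng.random(len(pi))
                d_total += int(np.sum(u < pi))
            for j in range(1, k):
                if config.couple_departures:
                    zb, u = pseudo_draws[j - 1]
                    nj = len(u)
                else:
                    nj = int(a_r[j - 1])
                    if nj == 0:
                        continue
                    if not len(pool):
                        raise ValueError(
                            "empty training pool for pseudo-subjects"
                        )
                    zb = pool[rng.integers(0, len(pool), nj)]
                    u = rng.random(nj)
                if nj == 0:
                    continue
                model = dep_models.models[(k - j, 0)]
                coef = coefs[(k - j, 0)]
                if model.covariate_names:
                    zs = (zb - model.x_mean) / model.x_scale
                    pi = expit(coef[0] + zs @ coef[1:])
                else:
                    pi = np.full(nj, expit(coef[0]))
                d_total += int(np.sum(u < pi))
            dep_reals[k][r] = d_total
            census_reals[k][r] = c_t + int(a_r[:k].sum()) - d_total

    point, lo, hi = {}, {}, {}
    for k in horizons:
        point[k], lo[k], hi[k] = summarize_ensemble(
            census_reals[k], config.point, config.quantiles
        )
    return ForecastResult(
        origin=state.day,
        horizons=horizons,
        realizations=census_reals,
        point=point,
        lo=lo,
        hi=hi,
        arrivals=arrivals_out,
        departures=dep_reals,
        seed=config.seed,
        census_at_origin=c_t,
    )


def _baseline_pool(records: Sequence[PatientRecord]) -> np.ndarray:
    pool = [
        [r.bweight, r.gestage]
        for r in records
        if r.bweight is not None and r.gestage is not None
    ]
    return np.asarray(pool, float) if pool else np.empty((0, 2))
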