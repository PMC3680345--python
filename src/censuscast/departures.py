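"""Departure-probability modelling.

The probability that a patient who has spent ``s`` days in the unit departs
within the next ``k`` days is modelled per (horizon k, stay-day stratum s)
with a logistic regression

    logit pi^(k)(Z, S=s) = Z(s) beta^(k,s)

on the covariates available at stay-day s.  The binary response is the
departure indicator

    Y^(k,s) = 1  iff  LOS <= k + s     (undefined when LOS <= s)

so a patient contributes one training row per stay-day it is at risk on,
provided the row's label is determined by the training cutoff (known LOS,
or censoring time >= k + s, which proves Y = 0).

Strata are s in {0, 1, ..., R-1} plus a pooled ">= R" stratum (default
R = 10) so that sparse long-stay days share one model.  Covariate
availability follows day-of-stay: birth weight and gestational age at
admission (s = 0); day-1 severity scores from s >= 1; the day-3 score from
s >= 3; the day-7 score from s >= 7.

Sparse or separated strata fall back, in order, to (i) pooling downward with
adjacent smaller-s strata (refit on the combined rows with the smaller
stratum's covariate set) and (ii) an intercept-only model at the stratum's
clamped empirical event rate.  All fits carry a small ridge penalty on
non-intercept terms (internally standardised covariates) and report the
inverse penalised observed information as the coefficient covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from ._glm import FitError, fit_logistic_ridge, mvn_factor
from .data_model import (
    BASELINE_COVARIATES,
    CensusState,
    PatientRecord,
    SCORE_AVAILABILITY,
    censor_record,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StratumSpec",
    "DepartureLabel",
    "DepartureModel",
    "DepartureModelSet",
    "TrainingTable",
    "make_label",
    "build_training_table",
    "fit_departure_models",
    "departure_prob",
    "sample_departures_in_census",
    "sample_pseudo_subjects",
]


@dataclass(frozen=True)
class StratumSpec:
    """Stay-day stratification: strata 0..R-1 plus the pooled '>= R'.

    The pooled stratum is identified by the integer ``max_stratum`` itself.
    """

    max_stratum: int = 10

    def __post_init__(self) -> None:
        if self.max_stratum < 1:
            raise ValueError("max_stratum must be >= 1")

    @property
    def strata(self) -> tuple[int, ...]:
        return tuple(range(self.max_stratum + 1))

    def stratum_of(self, s: int) -> int:
        if s < 0:
            raise ValueError("day-of-stay must be >= 0")
        return min(s, self.max_stratum)

    def covariate_names(self, stratum: int) -> tuple[str, ...]:
        """Covariates (excluding intercept) available at the stratum's
        smallest stay-day."""
        s = stratum
        names = list(BASELINE_COVARIATES)
        for name, avail in SCORE_AVAILABILITY.items():
            if s >= avail:
                names.append(name)
        return tuple(names)

    def is_pooled(self, stratum: int) -> bool:
        return stratum == self.max_stratum


@dataclass(frozen=True)
class DepartureLabel:
    patient_id: str
    k: int
    s: int
    y: Optional[int]  # None = indeterminable (not at risk, or censored)


def make_label(
    record: PatientRecord,
    k: int,
    s: int,
    cutoff_day: Optional[int] = None,
) -> DepartureLabel:
    """Label Y^(k,s) for one patient, using only information available by
    ``cutoff_day`` (if given).

    Undefined (``y=None``) when the patient was never at risk at stay-day s
    (LOS <= s) or when censoring leaves the outcome open.  A stay censored
    at c days proves LOS > c, hence Y = 0 whenever c >= k + s.
    """
    if k < 1 or s < 0:
        raise ValueError("require k >= 1 and s >= 0")
    rec = record if cutoff_day is None else censor_record(record, cutoff_day)
    if rec is None:
        return DepartureLabel(record.patient_id, k, s, None)
    if rec.los is not None:
        if rec.los <= s:
            y: Optional[int] = None
        else:
            y = 1 if rec.los <= k + s else 0
    else:
        y = 0 if rec.censored_at >= k + s else None
    return DepartureLabel(rec.patient_id, k, s, y)


@dataclass
class TrainingTable:
    """Labelled design rows for one (horizon, stratum) fit."""

    X: np.ndarray  # (n, d) including leading intercept column
    y: np.ndarray  # (n,) of 0/1
    covariate_names: tuple[str, ...]  # without intercept
    s_values: np.ndarray  # day-of-stay per row
    n_dropped_missing: int = 0

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_events(self) -> int:
        return int(self.y.sum())


def _rows_for_stratum(
    rec: PatientRecord, k: int, stratum: int, spec: StratumSpec
) -> list[int]:
    """Stay-days s in the stratum at which this record yields a defined label."""
    if spec.is_pooled(stratum):
        lo = spec.max_stratum
        if rec.los is not None:
            hi = rec.los - 1  # at risk while LOS > s
        else:
            hi = rec.censored_at - k  # need c >= k + s for a determined Y=0
        return list(range(lo, hi + 1))
    s = stratum
    return [s] if make_label(rec, k, s).y is not None else []


def build_training_table(
    records: Sequence[PatientRecord],
    k: int,
    stratum: int,
    spec: StratumSpec,
    cutoff_day: Optional[int] = None,
    *,
    covariate_names: Optional[tuple[str, ...]] = None,
) -> TrainingTable:
    """One design row per (patient, at-risk stay-day in the stratum) whose
    label is determined by the cutoff and whose covariates are complete.

    The pooled stratum contributes one row per defined (patient, s >= R)
    pair.  Rows never use covariate values unavailable at their stay-day;
    records missing a required covariate are dropped and counted.
    """
    if stratum not in spec.strata:
        raise ValueError(f"stratum {stratum} not in spec (R={spec.max_stratum})")
    names = covariate_names if covariate_names is not None else spec.covariate_names(stratum)
    if cutoff_day is not None:
        records = [
            r
            for r in (censor_record(rec, cutoff_day) for rec in records)
            if r is not None
        ]
    rows: list[list[float]] = []
    ys: list[int] = []
    svals: list[int] = []
    dropped = 0
    for rec in records:
        s_list = _rows_for_stratum(rec, k, stratum, spec)
        if not s_list:
            continue
        z = [rec.covariate(n) for n in names]
        if any(v is None for v in z):
            dropped += len(s_list)
            continue
        for s in s_list:
            lbl = make_label(rec, k, s)
            if lbl.y is None:  # pooled range is pre-filtered; defensive
                continue
            rows.append([1.0, *z])
            ys.append(lbl.y)
            svals.append(s)
    if dropped:
        logger.warning(
            "(k=%d, stratum=%d): dropped %d rows with missing covariates",
            k, stratum, dropped,
        )
    X = np.array(rows, float) if rows else np.empty((0, 1 + len(names)))
    return TrainingTable(
        X=X,
        y=np.array(ys, float),
        covariate_names=tuple(names),
        s_values=np.array(svals, int),
        n_dropped_missing=dropped,
    )


@dataclass
class DepartureModel:
    """Fitted departure-probability model for one (horizon, stratum).

    Coefficients are on the internally standardised covariate scale;
    ``x_mean``/``x_scale`` map raw covariates onto it at prediction time.
    """

    k: int
    stratum: int
    covariate_names: tuple[str, ...]
    coef: np.ndarray  # intercept + standardized-covariate coefficients
    cov: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    n: int
    n_events: int
    ridge: float
    fallback: Optional[str] = None  # None | "pooled:<level>" | "intercept_only"
    link: str = "logit"
    _chol: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def raw_coef(self) -> np.ndarray:
        """Coefficients mapped back to the original covariate scale."""
        return self._raw_transform() @ self.coef

    @property
    def raw_cov(self) -> np.ndarray:
        A = self._raw_transform()
        return A @ self.cov @ A.T

    def _raw_transform(self) -> np.ndarray:
        d = len(self.coef)
        A = np.zeros((d, d))
        A[0, 0] = 1.0
        if d > 1:
            A[0, 1:] = -self.x_mean / self.x_scale
            A[1:, 1:] = np.diag(1.0 / self.x_scale)
        return A

    def chol(self) -> np.ndarray:
        if self._chol is None:
            self._chol = mvn_factor(self.cov)
        return self._chol

    def sample_coefs(self, rng: np.random.Generator) -> np.ndarray:
        """beta^(r)(k,s) ~ MVN(beta_hat, V_beta)."""
        return self.coef + self.chol() @ rng.standard_normal(len(self.coef))

    def linear_predictor(self, z: np.ndarray, coef: Optional[np.ndarray] = None) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, float))
        if z.shape[1] != len(self.covariate_names):
            raise ValueError(
                f"(k={self.k}, stratum={self.stratum}): expected "
                f"{len(self.covariate_names)} covariates, got {z.shape[1]}"
            )
        b = self.coef if coef is None else np.asarray(coef, float)
        zs = (z - self.x_mean) / self.x_scale
        return b[0] + zs @ b[1:]


def departure_prob(
    model: DepartureModel,
    z: Sequence[float],
    coef: Optional[np.ndarray] = None,
) -> np.ndarray | float:
    """pi = inverse-logit of the linear predictor at raw covariates ``z``
    (one vector or a matrix of rows); optionally at sampled coefficients."""
    if model.link != "logit":
        raise NotImplementedError(f"link {model.link!r} not supported")
    eta = model.linear_predictor(z, coef)
    p = expit(eta)
    return float(p[0]) if np.ndim(z) == 1 else p


@dataclass
class DepartureModelSet:
    """All fitted (horizon, stratum) departure models plus their spec."""

    models: dict[tuple[int, int], DepartureModel]
    spec: StratumSpec
    horizons: tuple[int, ...]
    cutoff_day: Optional[int] = None

    def model_for(self, k: int, s: int) -> DepartureModel:
        key = (k, self.spec.stratum_of(s))
        if key not in self.models:
            raise KeyError(f"no departure model fitted for horizon {k}, s={s}")
        return self.models[key]

    @property
    def max_horizon(self) -> int:
        return max(self.horizons)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X[:, 1:].mean(axis=0) if len(X) else np.zeros(X.shape[1] - 1)
    scale = X[:, 1:].std(axis=0) if len(X) else np.ones(X.shape[1] - 1)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = X.copy()
    Xs[:, 1:] = (X[:, 1:] - mean) / scale
    return Xs, mean, scale


def _fit_one(
    table: TrainingTable, k: int, stratum: int, ridge: float,
    fallback: Optional[str],
) -> DepartureModel:
    Xs, mean, scale = _standardize(table.X)
    res = fit_logistic_ridge(Xs, table.y, ridge=ridge)
    return DepartureModel(
        k=k,
        stratum=stratum,
        covariate_names=table.covariate_names,
        coef=res.coef,
        cov=res.cov,
        x_mean=mean,
        x_scale=scale,
        n=table.n,
        n_events=table.n_events,
        ridge=ridge,
        fallback=fallback,
    )


def _intercept_only(
    table: TrainingTable, k: int, stratum: int, ridge: float
) -> DepartureModel:
    """Fallback of last resort: clamped empirical event rate with binomial
    information on the logit scale."""
    n, events = table.n, table.n_events
    p = (events + 1.0) / (n + 2.0)  # lies in [1/(n+2), 1 - 1/(n+2)]
    var = 1.0 / ((n + 2.0) * p * (1.0 - p))
    logger.warning(
        "(k=%d, stratum=%d): intercept-only fallback, n=%d events=%d p=%.3f",
        k, stratum, n, events, p,
    )
    return DepartureModel(
        k=k,
        stratum=stratum,
        covariate_names=(),
        coef=np.array([logit(p)]),
        cov=np.array([[var]]),
        x_mean=np.empty(0),
        x_scale=np.empty(0),
        n=n,
        n_events=events,
        ridge=ridge,
        fallback="intercept_only",
    )


def fit_departure_models(
    records: Sequence[PatientRecord],
    horizons: Sequence[int],
    spec: StratumSpec,
    cutoff_day: Optional[int] = None,
    *,
    ridge: float = 1e-4,
    min_rows: int = 10,
) -> DepartureModelSet:
    """Maximum-likelihood logistic fits for every (horizon, stratum).

    A stratum with fewer than ``min_rows`` usable rows or no variation in Y
    pools downward with adjacent smaller-s strata (combined rows, the lowest
    stratum's covariate set) and, failing that, uses the intercept-only
    fallback at its own clamped empirical rate.
    """
    if cutoff_day is not None:
        records = [
            r
            for r in (censor_record(rec, cutoff_day) for rec in records)
            if r is not None
        ]
        cutoff_for_set: Optional[int] = cutoff_day
    else:
        cutoff_for_set = None
    horizons = tuple(sorted(set(int(k) for k in horizons)))
    if not horizons or horizons[0] < 1:
        raise ValueError("horizons must be integers >= 1")
    models: dict[tuple[int, int], DepartureModel] = {}
    total_rows = 0
    for k in horizons:
        tables = {
            st: build_training_table(records, k, st, spec) for st in spec.strata
        }
        for st in spec.strata:
            table = tables[st]
            total_rows += table.n
            if _usable(table, min_rows):
                try:
                    models[(k, st)] = _fit_one(table, k, st, ridge, None)
                    continue
                except FitError as exc:
                    logger.warning("(k=%d, stratum=%d): %s", k, st, exc)
            fitted = None
            for low in range(st - 1, -1, -1):
                names = spec.covariate_names(low)
                combined = _combine_tables(
                    [_restrict(tables[j], names, spec) for j in range(low, st + 1)]
                )
                if not _usable(combined, min_rows):
                    continue
                try:
                    fitted = _fit_one(combined, k, st, ridge, f"pooled:{low}")
                    logger.warning(
                        "(k=%d, stratum=%d): pooled down to stratum %d (n=%d)",
                        k, st, low, combined.n,
                    )
                    break
                except FitError as exc:
                    logger.warning("(k=%d, stratum=%d pooled:%d): %s", k, st, low, exc)
            models[(k, st)] = (
                fitted if fitted is not None else _intercept_only(table, k, st, ridge)
            )
    if total_rows == 0:
        raise FitError("no (horizon, stratum) had any usable training data")
    return DepartureModelSet(
        models=models, spec=spec, horizons=horizons, cutoff_day=cutoff_for_set
    )


def _usable(table: TrainingTable, min_rows: int) -> bool:
    return table.n >= min_rows and 0 < table.n_events < table.n


def _restrict(
    table: TrainingTable, names: tuple[str, ...], spec: StratumSpec
) -> TrainingTable:
    """Project a table onto a smaller covariate set (for pooled refits)."""
    idx = [0] + [1 + table.covariate_names.index(n) for n in names]
    return TrainingTable(
        X=table.X[:, idx],
        y=table.y,
        covariate_names=names,
        s_values=table.s_values,
        n_dropped_missing=table.n_dropped_missing,
    )


def _combine_tables(tables: list[TrainingTable]) -> TrainingTable:
    names = tables[0].covariate_names
    return TrainingTable(
        X=np.vstack([t.X for t in tables]),
        y=np.concatenate([t.y for t in tables]),
        covariate_names=names,
        s_values=np.concatenate([t.s_values for t in tables]),
        n_dropped_missing=sum(t.n_dropped_missing for t in tables),
    )


def _covariates_for(rec: PatientRecord, model: DepartureModel) -> np.ndarray:
    z = []
    for name in model.covariate_names:
        v = rec.covariate(name)
        if v is None:
            raise ValueError(
                f"patient {rec.patient_id}: covariate {name!r} required by the "
                f"(k={model.k}, stratum={model.stratum}) model is missing"
            )
        z.append(v)
    return np.asarray(z, float)


def sample_departures_in_census(
    state: CensusState,
    model_set: DepartureModelSet,
    k: int,
    rng: np.random.Generator,
    *,
    coef_overrides: Optional[dict[tuple[int, int], np.ndarray]] = None,
) -> tuple[np.ndarray, int]:
    """Bernoulli departure draws Y-hat_i^(k,s) for every patient in the
    census, and their sum D-hat(t+k) over all strata (never exceeds C(t)).

    ``coef_overrides`` maps (k, stratum) to sampled coefficient vectors for
    ensemble use.
    """
    draws = np.zeros(state.census_count, dtype=int)
    for i, (rec, s) in enumerate(state.present):
        model = model_set.model_for(k, s)
        coef = None
        if coef_overrides is not None:
            coef = coef_overrides.get((k, model.stratum))
        if model.covariate_names:
            z = _covariates_for(rec, model)
            pi = departure_prob(model, z, coef)
        else:
            b = model.coef if coef is None else coef
            pi = float(expit(b[0]))
        draws[i] = int(rng.random() < pi)
    return draws, int(draws.sum())


def sample_pseudo_subjects(
    records: Sequence[PatientRecord], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Resample ``n`` baseline covariate pairs (bweight, gestage) jointly,
    with replacement, from the training pool — the 'pseudo-subjects' that
    stand in for not-yet-arrived patients."""
    if n < 0:
        raise ValueError("n must be >= 0")
    pool = np.array(
        [
            [r.bweight, r.gestage]
            for r in records
            if r.bweight is not None and r.gestage is not None
        ],
        float,
    )
    if n == 0:
        return np.empty((0, 2))
    if len(pool) == 0:
        raise ValueError("empty training pool: no baseline covariates to resample")
    idx = rng.integers(0, len(pool), size=n)
    return pool[idx]
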