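"""Seasonality-adjusted Poisson autoregressive (PAR) model for daily arrivals.

The conditional mean of the order-p model with K harmonics is

    log mu_t = beta_0 + sum_k [phi_k cos(2 pi t w_k / T) + alpha_k sin(...)]
             + sum_{i=1..p} beta_i A(t - i)

with t = 1..T the 1-based day index and w_k an integer number of cycles per
the reference length T.  Parameters are estimated by conditional maximum
likelihood, treating the first p (or a common p_max window during order
selection) arrival counts as fixed; the parameter covariance is the inverse
observed Fisher information at the optimum.  The stacked parameter vector is
lam = [beta_0, beta_1..beta_p, phi_1, alpha_1, ..., phi_K, alpha_K].

The reference length ``T`` is frozen in :class:`HarmonicSpec` when the
frequency is chosen, so the physical period ``T / w_k`` days stays fixed when
the model is refit on a longer (expanding-window) series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._glm import (
    ETA_CLIP,
    FitError,
    fit_poisson_loglinear,
    mvn_factor,
    poisson_loglik,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonicSpec",
    "PARFit",
    "conditional_mean",
    "fit_par",
    "select_order_bic",
    "estimate_frequency",
    "sample_arrival_params",
    "simulate_arrivals",
]


@dataclass(frozen=True)
class HarmonicSpec:
    """Harmonic seasonality specification.

    ``frequencies`` are cycles per ``series_length`` days; ``series_length``
    is the reference T frozen at specification time, so each harmonic has a
    fixed physical period of ``series_length / frequency`` days.
    """

    n_harmonics: int
    frequencies: tuple[float, ...]
    series_length: int

    def __post_init__(self) -> None:
        if self.n_harmonics != len(self.frequencies):
            raise ValueError("n_harmonics must equal len(frequencies)")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("frequencies must be positive")
        if self.series_length < 1:
            raise ValueError("series_length must be >= 1")

    @property
    def periods(self) -> tuple[float, ...]:
        """Period of each harmonic in days."""
        return tuple(self.series_length / f for f in self.frequencies)

    def basis(self, t: np.ndarray) -> np.ndarray:
        """Columns [cos_1, sin_1, ..., cos_K, sin_K] at 1-based days t."""
        t = np.atleast_1d(np.asarray(t, float))
        cols = []
        for f in self.frequencies:
            ang = 2.0 * np.pi * t * f / self.series_length
            cols.append(np.cos(ang))
            cols.append(np.sin(ang))
        if not cols:
            return np.empty((len(t), 0))
        return np.column_stack(cols)


def no_seasonality(series_length: int) -> HarmonicSpec:
    return HarmonicSpec(0, (), series_length)


@dataclass(frozen=True)
class PARFit:
    """Fitted seasonality-adjusted PAR model."""

    order: int
    intercept: float
    ar_coefs: tuple[float, ...]
    cos_coefs: tuple[float, ...]
    sin_coefs: tuple[float, ...]
    param_cov: np.ndarray
    log_lik: float
    bic: float
    harmonic: HarmonicSpec
    n_effective: int

    @property
    def params(self) -> np.ndarray:
        """Stacked vector [beta_0, beta_1..p, phi_1, alpha_1, ...]."""
        interleaved: list[float] = []
        for c, s in zip(self.cos_coefs, self.sin_coefs):
            interleaved += [c, s]
        return np.array([self.intercept, *self.ar_coefs, *interleaved])

    def __post_init__(self) -> None:
        d = 1 + self.order + 2 * self.harmonic.n_harmonics
        if self.param_cov.shape != (d, d):
            raise ValueError(
                f"param_cov shape {self.param_cov.shape} != ({d}, {d})"
            )


def _split_params(params: np.ndarray, p: int, harmonic: HarmonicSpec):
    beta0 = params[0]
    ar = params[1 : 1 + p]
    harm = params[1 + p :]
    return beta0, ar, harm


def conditional_mean(
    params: np.ndarray | PARFit,
    lagged_counts: Sequence[float],
    t: int,
    harmonic: Optional[HarmonicSpec] = None,
    order: Optional[int] = None,
) -> float:
    """Evaluate mu_t given the p most recent counts (most-recent-first).

    ``params`` may be a :class:`PARFit` or a stacked parameter vector (in
    which case ``harmonic`` and ``order`` are required).  The linear
    predictor is clipped to +/-30 before exponentiation.
    """
    if isinstance(params, PARFit):
        harmonic = params.harmonic
        order = params.order
        vec = params.params
    else:
        if harmonic is None or order is None:
            raise ValueError("harmonic and order required with a raw vector")
        vec = np.asarray(params, float)
    lags = np.asarray(lagged_counts, float)
    if lags.shape != (order,):
        raise ValueError(f"expected {order} lagged counts, got {lags.shape}")
    beta0, ar, harm = _split_params(vec, order, harmonic)
    eta = beta0 + float(ar @ lags) + float(harmonic.basis(t)[0] @ harm)
    if abs(eta) > ETA_CLIP:
        logger.warning("linear predictor %.2f clipped to +/-%.0f", eta, ETA_CLIP)
        eta = float(np.clip(eta, -ETA_CLIP, ETA_CLIP))
    return float(np.exp(eta))


def _design(
    series: np.ndarray, p: int, harmonic: HarmonicSpec, t_start: int
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and response for conditional days t = t_start..T
    (1-based).  Columns: intercept, lags 1..p, harmonic basis."""
    T = len(series)
    t = np.arange(t_start, T + 1)
    y = series[t - 1]
    cols = [np.ones(len(t))]
    for i in range(1, p + 1):
        cols.append(series[t - 1 - i])
    X = np.column_stack(cols)
    basis = harmonic.basis(t)
    if basis.shape[1]:
        X = np.hstack([X, basis])
    return X, y.astype(float)


def _validate_series(series: Sequence[float]) -> np.ndarray:
    arr = np.asarray(series)
    if arr.ndim != 1 or len(arr) == 0:
        raise ValueError("series must be a nonempty 1-d sequence")
    if np.any(arr < 0) or np.any(arr != np.round(arr)):
        raise ValueError("arrival counts must be nonnegative integers")
    return arr.astype(float)


def fit_par(
    series: Sequence[float],
    p: int,
    harmonic: Optional[HarmonicSpec] = None,
    *,
    n_condition: Optional[int] = None,
) -> PARFit:
    """Conditional maximum likelihood fit of the seasonal PAR(p) model.

    ``n_condition`` (default ``p``) is the number of initial observations
    treated as fixed; order selection passes a common ``p_max`` here so that
    candidate likelihoods are comparable.
    """
    arr = _validate_series(series)
    T = len(arr)
    if harmonic is None:
        harmonic = no_seasonality(T)
    if n_condition is None:
        n_condition = p
    if n_condition < p:
        raise ValueError("n_condition must be >= p")
    d = 1 + p + 2 * harmonic.n_harmonics
    n_eff = T - n_condition
    if n_eff <= d:
        raise ValueError(
            f"series too short: {n_eff} usable days for {d} parameters"
        )
    X, y = _design(arr, p, harmonic, n_condition + 1)
    res = fit_poisson_loglinear(X, y)
    K = harmonic.n_harmonics
    harm = res.coef[1 + p :]
    bic = -2.0 * res.log_lik + d * np.log(n_eff)
    return PARFit(
        order=p,
        intercept=float(res.coef[0]),
        ar_coefs=tuple(res.coef[1 : 1 + p]),
        cos_coefs=tuple(harm[0::2][:K]),
        sin_coefs=tuple(harm[1::2][:K]),
        param_cov=res.cov,
        log_lik=res.log_lik,
        bic=float(bic),
        harmonic=harmonic,
        n_effective=n_eff,
    )


def select_order_bic(
    series: Sequence[float],
    p_max: int,
    harmonic: Optional[HarmonicSpec] = None,
) -> tuple[int, list[tuple[int, float]]]:
    """Choose the autoregressive order by BIC on a common conditioning window.

    Every candidate order p = 0..p_max is fit conditioning on the first
    ``p_max`` observations, so the likelihoods (hence BICs) are comparable.
    Ties break toward the smaller order; orders whose fit fails are skipped
    with a warning.
    """
    if p_max < 0:
        raise ValueError("p_max must be >= 0")
    table: list[tuple[int, float]] = []
    for p in range(p_max + 1):
        try:
            fit = fit_par(series, p, harmonic, n_condition=p_max)
        except FitError as exc:
            logger.warning("order %d skipped: %s", p, exc)
            continue
        table.append((p, fit.bic))
    if not table:
        raise FitError("no candidate order could be fit")
    best = min(table, key=lambda pb: (pb[1], pb[0]))[0]
    return best, table


def estimate_frequency(
    series: Sequence[float], candidate_freqs: Sequence[int]
) -> tuple[int, np.ndarray]:
    """Pick the seasonal frequency as the candidate (integer cycles per
    series) maximising the periodogram of the mean-centred series.

    This automates the visual inspection of the sample autocorrelation
    function's cyclical pattern; the sample ACF is returned alongside for
    plotting.  On a white-noise series the argmax is returned but carries no
    evidence of seasonality — the caller decides whether to use harmonics.
    """
    arr = np.asarray(series, float)
    if len(candidate_freqs) == 0:
        raise ValueError("candidate_freqs must be nonempty")
    if np.ptp(arr) == 0:
        raise ValueError("constant series has no identifiable frequency")
    T = len(arr)
    x = arr - arr.mean()
    t = np.arange(1, T + 1)
    best_f, best_power = None, -np.inf
    for f in candidate_freqs:
        if f < 1:
            raise ValueError("candidate frequencies must be >= 1 cycle")
        ang = 2.0 * np.pi * t * f / T
        power = (x @ np.cos(ang)) ** 2 + (x @ np.sin(ang)) ** 2
        if power > best_power:
            best_f, best_power = int(f), power
    from statsmodels.tsa.stattools import acf

    sample_acf = acf(arr, nlags=min(T - 1, max(10, T // 2)), fft=True)
    return best_f, sample_acf


def sample_arrival_params(fit: PARFit, rng: np.random.Generator) -> np.ndarray:
    """One draw lam^(r) ~ MVN(lam_hat, V_lam) of the stacked parameters."""
    return fit.params + mvn_factor(fit.param_cov) @ rng.standard_normal(
        len(fit.params)
    )


def simulate_arrivals(
    fit: PARFit,
    history: Sequence[float],
    horizon: int,
    rng: np.random.Generator,
    *,
    params: Optional[np.ndarray] = None,
    t_origin: Optional[int] = None,
) -> np.ndarray:
    """Sequentially sample arrivals A(t+1)..A(t+horizon).

    Lags use observed history through the origin day and previously sampled
    counts beyond it; each count is Poisson with mean from the conditional
    mean at (possibly sampled) parameters ``params``.  ``t_origin`` is the
    1-based day index of the last history observation (defaults to
    ``len(history)``).
    """
    hist = np.asarray(history, float)
    if len(hist) < fit.order:
        raise ValueError(
            f"history of length {len(hist)} shorter than order {fit.order}"
        )
    vec = fit.params if params is None else np.asarray(params, float)
    t0 = len(hist) if t_origin is None else t_origin
    out = np.empty(horizon, dtype=int)
    lags = hist[len(hist) - fit.order :][::-1].copy() if fit.order else np.empty(0)
    for j in range(1, horizon + 1):
        mu = conditional_mean(
            vec, lags, t0 + j, harmonic=fit.harmonic, order=fit.order
        )
        a = rng.poisson(mu)
        out[j - 1] = a
        if fit.order:
            lags = np.concatenate(([a], lags[:-1]))
    return out
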