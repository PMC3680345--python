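"""Newton-Raphson fitting for the two log-likelihoods the method maximises.

Both models use canonical links, so the analytic Hessian equals the observed
Fisher information and the parameter covariance is its inverse at the
optimum.  Damped Newton steps (step-halving on the objective) are enough for
these concave problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln

logger = logging.getLogger(__name__)

#: bound on the linear predictor before exponentiation; extreme multivariate
#: normal parameter draws can otherwise overflow exp().
ETA_CLIP = 30.0


class FitError(RuntimeError):
    """Raised when a likelihood maximisation fails to converge."""


@dataclass
class GLMResult:
    coef: np.ndarray
    cov: np.ndarray          # inverse (penalised) observed information
    log_lik: float           # unpenalised log-likelihood at the optimum
    n_iter: int
    converged: bool


def poisson_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Poisson log-linear log-likelihood, including the log y! constant."""
    eta = np.clip(X @ beta, -ETA_CLIP, ETA_CLIP)
    mu = np.exp(eta)
    return float(np.sum(y * eta - mu - gammaln(y + 1.0)))


def fit_poisson_loglinear(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> GLMResult:
    """Maximum likelihood for a Poisson regression with log link."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    beta = np.zeros(d)
    beta[0] = np.log(max(y.mean(), 1e-8)) if np.allclose(X[:, 0], 1.0) else 0.0
    ll = poisson_loglik(beta, X, y)
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        H = X.T @ (mu[:, None] * X)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step-halving line search on the log-likelihood
        alpha = 1.0
        for _ in range(40):
            ll_new = poisson_loglik(beta + alpha * step, X, y)
            if ll_new >= ll - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        improved = ll_new - ll
        ll = ll_new
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)) or improved < tol:
            eta = np.clip(X @ beta, -ETA_CLIP, ETA_CLIP)
            mu = np.exp(eta)
            info = X.T @ (mu[:, None] * X)
            return GLMResult(beta, _safe_inverse(info), ll, it, True)
    raise FitError(
        f"Poisson fit did not converge in {max_iter} iterations "
        f"(n={n}, d={d}, |grad|_inf={np.max(np.abs(grad)):.3g})"
    )


def logistic_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    # log(1 + exp(eta)) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_ridge(
    X: np.ndarray,
    y: np.ndarray,
    *,
    ridge: float = 1e-4,
    penalize_intercept: bool = False,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> GLMResult:
    """Logistic regression by penalised Newton-Raphson.

    The ridge term (0.5 * ridge * sum beta_j^2 over non-intercept terms by
    default) stabilises separated or near-separated strata; the covariance
    reported is the inverse of the penalised observed information.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape
    pen = np.full(d, ridge)
    if not penalize_intercept and np.allclose(X[:, 0], 1.0):
        pen[0] = 0.0
    D = np.diag(pen)

    def objective(b: np.ndarray) -> float:
        return logistic_loglik(b, X, y) - 0.5 * float(b @ (pen * b))

    beta = np.zeros(d)
    obj = objective(beta)
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        grad = X.T @ (y - p) - pen * beta
        w = p * (1.0 - p)
        H = X.T @ (w[:, None] * X) + D
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        alpha = 1.0
        for _ in range(40):
            obj_new = objective(beta + alpha * step)
            if obj_new >= obj - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        improved = obj_new - obj
        obj = obj_new
        if np.max(np.abs(grad)) < tol * max(1.0, abs(obj)) or improved < tol:
            p = expit(X @ beta)
            w = p * (1.0 - p)
            info = X.T @ (w[:, None] * X) + D
            return GLMResult(
                beta, _safe_inverse(info), logistic_loglik(beta, X, y), it, True
            )
    raise FitError(
        f"logistic fit did not converge in {max_iter} iterations (n={n}, d={d})"
    )


def _safe_inverse(info: np.ndarray) -> np.ndarray:
    """Invert an information matrix, symmetrising and adding one round of
    tiny jitter (1e-8 * trace/dim) if it is not positive definite."""
    info = 0.5 * (info + info.T)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(info) / info.shape[0]
        logger.warning("information matrix singular; adding jitter %.3g", jitter)
        cov = np.linalg.inv(info + jitter * np.eye(info.shape[0]))
    return 0.5 * (cov + cov.T)


def sample_mvn(
    mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One multivariate-normal draw via Cholesky, tolerating PSD covariances.

    A zero covariance returns the mean exactly.  Non-PSD covariances are
    symmetrised and jittered once (1e-8 * trace/dim) before erroring.
    """
    return mean + mvn_factor(cov) @ rng.standard_normal(len(mean))


def mvn_factor(cov: np.ndarray) -> np.ndarray:
    """A matrix L with L L^T = cov (Cholesky, with PSD fallback)."""
    cov = 0.5 * (np.asarray(cov, float) + np.asarray(cov, float).T)
    if not np.any(cov):
        return np.zeros_like(cov)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * max(np.trace(cov), 1e-30) / cov.shape[0]
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
            logger.warning("covariance not PD; jitter %.3g applied", jitter)
            return L
        except np.linalg.LinAlgError:
            # PSD with exact zero directions: eigen route
            vals, vecs = np.linalg.eigh(cov)
            if vals.min() < -1e-8 * max(vals.max(), 1.0):
                raise np.linalg.LinAlgError(
                    f"covariance has negative eigenvalue {vals.min():.3g}"
                )
            return vecs * np.sqrt(np.clip(vals, 0.0, None))
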