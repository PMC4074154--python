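"""Gaussian process regression with marginal-likelihood training.

Covariances (Gram matrices get a noise term sigma_n^2 * I on the diagonal):

    linear:       k(x, z) = sigma^2 * (1 + <x, z>)
    squared exp.: k(x, z) = sigma^2 * exp(-||x - z||^2 / (2 l^2))

The empirical mean of the targets is subtracted before training; the
hyperparameters maximize the log marginal likelihood

    L = -1/2 log|S| - 1/2 (y-mu)^T S^-1 (y-mu) - m/2 log(2 pi)

by quasi-Newton ascent (L-BFGS-B) in log-parameter space with analytic
gradients and a fixed set of multistart initializations.  All linear
algebra goes through a Cholesky factor of the training covariance; when a
candidate covariance is numerically indefinite, a relative jitter is
escalated from 1e-10 to 1e-6 before the candidate is rejected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.spatial.distance import cdist

from .errors import (
    DimensionMismatchError,
    InvalidInputError,
    NonPositiveDefiniteError,
)

__all__ = [
    "Covariance",
    "CovarianceSpec",
    "GPModel",
    "covariance_matrix",
    "log_marginal_likelihood",
    "gpr_train",
    "gpr_predict",
]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)


class Covariance(enum.Enum):
    LINEAR = "linear"
    SQEXP = "sqexp"


@dataclass(frozen=True)
class CovarianceSpec:
    """Covariance kind with signal variance, length scale and noise variance."""

    kind: Covariance
    signal_variance: float
    length_scale: Optional[float] = None
    noise_variance: float = 0.0

    def __post_init__(self) -> None:
        if self.signal_variance <= 0:
            raise InvalidInputError("signal_variance must be positive")
        if self.noise_variance < 0:
            raise InvalidInputError("noise_variance must be nonnegative")
        if self.kind is Covariance.SQEXP and (
            self.length_scale is None or self.length_scale <= 0
        ):
            raise InvalidInputError("SQEXP covariance requires length_scale > 0")


def covariance_matrix(X, Z, cov: CovarianceSpec, add_noise: bool = False) -> np.ndarray:
    """Covariance k(x_i, z_j); adds sigma_n^2 * I when ``add_noise`` (square only)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise DimensionMismatchError(f"column mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if cov.kind is Covariance.LINEAR:
        K = cov.signal_variance * (1.0 + X @ Z.T)
    else:
        sq = cdist(X, Z, "sqeuclidean")
        K = cov.signal_variance * np.exp(-sq / (2.0 * cov.length_scale**2))
    if add_noise:
        if K.shape[0] != K.shape[1]:
            raise DimensionMismatchError("noise can only be added to a square covariance")
        K = K + cov.noise_variance * np.eye(K.shape[0])
    return K


def _chol_with_jitter(S: np.ndarray) -> tuple[np.ndarray, float]:
    scale = float(np.mean(np.diag(S))) or 1.0
    for jit in _JITTERS:
        try:
            L = np.linalg.cholesky(S + jit * scale * np.eye(S.shape[0]))
            return L, jit
        except np.linalg.LinAlgError:
            continue
    raise NonPositiveDefiniteError("covariance matrix is not positive definite")


def log_marginal_likelihood(X, y, cov: CovarianceSpec) -> float:
    """Log probability of the targets under the GP prior (constant-mean)."""
    y = np.asarray(y, dtype=float)
    m = len(y)
    S = covariance_matrix(X, X, cov, add_noise=True)
    L, _ = _chol_with_jitter(S)
    resid = y - y.mean()
    z = scipy.linalg.solve_triangular(L, resid, lower=True)
    return float(
        -np.log(np.diag(L)).sum() - 0.5 * z @ z - 0.5 * m * math.log(2.0 * math.pi)
    )


@dataclass
class GPModel:
    """A trained Gaussian process regressor."""

    cov: CovarianceSpec
    training_inputs: np.ndarray
    target_mean: float
    centered_targets: np.ndarray
    chol: np.ndarray
    alpha_vec: np.ndarray
    log_marginal: float


def _pack(cov: CovarianceSpec) -> np.ndarray:
    if cov.kind is Covariance.SQEXP:
        return np.log([cov.signal_variance, cov.length_scale, max(cov.noise_variance, 1e-300)])
    return np.log([cov.signal_variance, max(cov.noise_variance, 1e-300)])


def _unpack(kind: Covariance, theta: np.ndarray) -> CovarianceSpec:
    if kind is Covariance.SQEXP:
        return CovarianceSpec(kind, math.exp(theta[0]), math.exp(theta[1]), math.exp(theta[2]))
    return CovarianceSpec(kind, math.exp(theta[0]), None, math.exp(theta[1]))


def _neg_lml_and_grad(theta: np.ndarray, kind: Covariance, X, resid, sqd):
    """-L and its gradient w.r.t. the log-parameters."""
    m = len(resid)
    sig2 = math.exp(theta[0])
    if kind is Covariance.SQEXP:
        ell = math.exp(theta[1])
        noise = math.exp(theta[2])
        M = np.exp(-sqd / (2.0 * ell * ell))
        K = sig2 * M
    else:
        noise = math.exp(theta[1])
        M = 1.0 + X @ X.T
        K = sig2 * M
    S = K + noise * np.eye(m)
    try:
        L, _ = _chol_with_jitter(S)
    except NonPositiveDefiniteError:
        return np.inf, np.zeros_like(theta)
    alpha = scipy.linalg.cho_solve((L, True), resid)
    lml = (
        -np.log(np.diag(L)).sum()
        - 0.5 * resid @ alpha
        - 0.5 * m * math.log(2.0 * math.pi)
    )
    Sinv = scipy.linalg.cho_solve((L, True), np.eye(m))
    W = np.outer(alpha, alpha) - Sinv
    # dL/dtheta_j = 1/2 tr(W dS/dtheta_j)
    grad = np.empty_like(theta)
    grad[0] = 0.5 * np.sum(W * K)  # dS/dlog sig2 = K
    if kind is Covariance.SQEXP:
        dS_dlogl = K * (sqd / (ell * ell))
        grad[1] = 0.5 * np.sum(W * dS_dlogl)
        grad[2] = 0.5 * noise * np.trace(W)
    else:
        grad[1] = 0.5 * noise * np.trace(W)
    return -lml, -grad


def gpr_train(
    X,
    y,
    kind: Covariance,
    n_starts: int = 5,
    seed: int = 0,
    max_iter: int = 200,
) -> GPModel:
    """Fit GP hyperparameters by maximizing the marginal likelihood.

    Multistart L-BFGS-B in log-parameter space; initializations are drawn
    from data-scaled ranges with a seeded generator, so training is
    deterministic.  The best stationary point over all starts is returned.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    m = len(y)
    if m < 3:
        raise InvalidInputError("GP training needs at least three points")
    if len(X) != m:
        raise DimensionMismatchError("X and y length mismatch")
    mu = float(y.mean())
    resid = y - mu
    var_y = float(resid.var()) or 1.0
    sqd = cdist(X, X, "sqeuclidean") if kind is Covariance.SQEXP else None
    if kind is Covariance.SQEXP:
        med = float(np.median(sqd[sqd > 0])) if np.any(sqd > 0) else 1.0
        ell0 = math.sqrt(med)
    rng = np.random.default_rng(seed)

    best = None
    for start in range(n_starts):
        if kind is Covariance.SQEXP:
            theta0 = np.array([
                math.log(var_y) + rng.uniform(-1, 1),
                math.log(ell0) + rng.uniform(-1.5, 1.5),
                math.log(var_y) + rng.uniform(-12, -2),
            ])
        else:
            theta0 = np.array([
                math.log(var_y) + rng.uniform(-2, 2),
                math.log(var_y) + rng.uniform(-12, -2),
            ])
        res = scipy.optimize.minimize(
            _neg_lml_and_grad,
            theta0,
            args=(kind, X, resid, sqd),
            method="L-BFGS-B",
            jac=True,
            bounds=[(-40.0, 40.0)] * len(theta0),
            options={"maxiter": max_iter},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise NonPositiveDefiniteError("no multistart produced a valid covariance")

    cov = _unpack(kind, best.x)
    S = covariance_matrix(X, X, cov, add_noise=True)
    L, _ = _chol_with_jitter(S)
    alpha = scipy.linalg.cho_solve((L, True), resid)
    return GPModel(
        cov=cov,
        training_inputs=X,
        target_mean=mu,
        centered_targets=resid,
        chol=L,
        alpha_vec=alpha,
        log_marginal=float(-best.fun),
    )


def gpr_predict(model: GPModel, Xnew) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian posterior mean and variance at new inputs.

    mean = mu + K*^T S^-1 (y - mu);  var = diag(K**) - diag(K*^T S^-1 K*),
    both evaluated through the stored Cholesky factor.  Variances are
    clipped at zero against roundoff.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    Kstar = covariance_matrix(model.training_inputs, Xnew, model.cov)
    mean = model.target_mean + Kstar.T @ model.alpha_vec
    v = scipy.linalg.solve_triangular(model.chol, Kstar, lower=True)
    if model.cov.kind is Covariance.SQEXP:
        kss = np.full(len(Xnew), model.cov.signal_variance)
    else:
        kss = model.cov.signal_variance * (1.0 + np.sum(Xnew * Xnew, axis=1))
    var = np.maximum(kss - np.sum(v * v, axis=0), 0.0)
    return mean, var
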