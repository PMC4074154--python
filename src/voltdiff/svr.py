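"""Support vector regression with the epsilon-insensitive quadratic loss.

The regression function f(x) = sum_i beta_i k(x_i, x) + b is found by
minimizing the primal objective

    beta^T K beta + C * sum_i max(0, |r_i| - eps)^2 ,   r_i = K_i beta + b - y_i,

directly over (beta, b) with a damped Newton iteration.  Residuals of
magnitude at most eps incur zero loss (the flat-bottomed parabola), which
makes the objective piecewise quadratic and continuously differentiable, so
Newton steps on the active set converge quickly.  With eps = 0 the problem
reduces to kernel ridge regression with penalty 1/C and the solver must
reproduce its closed-form solution.

Hyperparameters (C, eps and the RBF width gamma) are chosen by k-fold
cross-validated mean squared error over a log-spaced grid, followed by a
local Nelder-Mead refinement; the fold assignment is seeded, so selection
is deterministic.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize
from scipy.spatial.distance import cdist

from .errors import DimensionMismatchError, InvalidInputError

__all__ = [
    "Kernel",
    "KernelSpec",
    "SVRModel",
    "kernel_matrix",
    "svr_objective",
    "svr_train",
    "svr_predict",
    "select_hyperparameters",
]


class Kernel(enum.Enum):
    LINEAR = "linear"
    RBF = "rbf"


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind plus the RBF width gamma (k(x,z) = exp(-gamma*||x-z||^2))."""

    kind: Kernel
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is Kernel.RBF:
            if self.gamma is None or self.gamma <= 0:
                raise InvalidInputError("RBF kernel requires gamma > 0")
        elif self.gamma is not None:
            raise InvalidInputError("gamma is only meaningful for the RBF kernel")


def kernel_matrix(X, Z, spec: KernelSpec) -> np.ndarray:
    """Gram matrix k(x_i, z_j) for rows of X and Z."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise DimensionMismatchError(
            f"column mismatch: {X.shape[1]} vs {Z.shape[1]}"
        )
    if spec.kind is Kernel.LINEAR:
        return X @ Z.T
    sq = cdist(X, Z, "sqeuclidean")
    return np.exp(-spec.gamma * sq)


def svr_objective(beta, b: float, K, y, C: float, epsilon: float) -> float:
    """Primal objective beta^T K beta + C * sum max(0, |r|-eps)^2."""
    beta = np.asarray(beta, dtype=float)
    r = K @ beta + b - np.asarray(y, dtype=float)
    excess = np.maximum(0.0, np.abs(r) - epsilon)
    return float(beta @ (K @ beta) + C * np.sum(excess**2))


@dataclass
class SVRModel:
    """A trained support vector regressor (primal form)."""

    beta: np.ndarray
    bias: float
    kernel: KernelSpec
    training_inputs: np.ndarray
    C: float
    epsilon: float
    converged: bool = True
    n_iterations: int = 0
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _newton_solve(K, y, C, epsilon, max_iter, tol):
    m = len(y)
    beta = np.zeros(m)
    b = float(np.mean(y))
    obj = svr_objective(beta, b, K, y, C, epsilon)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        r = K @ beta + b - y
        active = np.abs(r) > epsilon
        s = np.where(active, r - epsilon * np.sign(r), 0.0)
        grad_beta = 2.0 * (K @ beta) + 2.0 * C * (K[active].T @ s[active])
        grad_b = 2.0 * C * s.sum()
        grad = np.concatenate([grad_beta, [grad_b]])
        gnorm = np.linalg.norm(grad)
        if gnorm <= 1e-12 * (1.0 + abs(obj)):
            converged = True
            break

        KA = K[active]
        H = np.empty((m + 1, m + 1))
        H[:m, :m] = 2.0 * K + 2.0 * C * (KA.T @ KA)
        cross = 2.0 * C * KA.sum(axis=0)
        H[:m, m] = cross
        H[m, :m] = cross
        H[m, m] = 2.0 * C * active.sum()

        lam = 0.0
        scale = np.trace(H) / (m + 1) + 1e-30
        step = None
        for _ in range(40):
            try:
                Hd = H if lam == 0.0 else H + lam * scale * np.eye(m + 1)
                step = np.linalg.solve(Hd, -grad)
                if np.dot(step, grad) < 0:  # descent direction
                    break
            except np.linalg.LinAlgError:
                pass
            lam = 10.0 * lam if lam > 0 else 1e-10
        if step is None or not np.all(np.isfinite(step)):
            break

        # backtracking line search: the objective never increases
        t = 1.0
        new_obj = obj
        for _ in range(60):
            nb = beta + t * step[:m]
            nbias = b + t * step[m]
            new_obj = svr_objective(nb, nbias, K, y, C, epsilon)
            if new_obj <= obj:
                break
            t *= 0.5
        if new_obj > obj:
            break
        beta, b = beta + t * step[:m], b + t * step[m]
        decrease = obj - new_obj
        obj = new_obj
        trace.append(obj)
        if decrease <= tol * (1.0 + abs(obj)):
            converged = True
            break
    return beta, b, converged, it, np.asarray(trace)


def svr_train(
    X,
    y,
    spec: KernelSpec,
    C: float,
    epsilon: float,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SVRModel:
    """Train an SVR model by damped Newton iteration on the primal objective.

    Returns a stationary point of :func:`svr_objective`; the objective is
    nonincreasing across iterations.  If ``max_iter`` is exhausted the model
    is still returned, flagged ``converged=False`` with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise DimensionMismatchError("X and y length mismatch")
    if len(y) < 2:
        raise InvalidInputError("need at least two training points")
    if C <= 0:
        raise InvalidInputError("C must be positive")
    if epsilon < 0:
        raise InvalidInputError("epsilon must be nonnegative")
    K = kernel_matrix(X, X, spec)
    beta, b, converged, n_iter, trace = _newton_solve(K, y, C, epsilon, max_iter, tol)
    if not converged:
        warnings.warn("SVR Newton iteration did not converge; returning best iterate")
    return SVRModel(
        beta=beta,
        bias=b,
        kernel=spec,
        training_inputs=X,
        C=C,
        epsilon=epsilon,
        converged=converged,
        n_iterations=n_iter,
        objective_trace=trace,
    )


def svr_predict(model: SVRModel, Xnew) -> np.ndarray:
    """Evaluate the trained regressor at new inputs."""
    Knew = kernel_matrix(np.atleast_2d(np.asarray(Xnew, dtype=float)),
                         model.training_inputs, model.kernel)
    return Knew @ model.beta + model.bias


def _cv_mse(X, y, spec, C, epsilon, folds) -> float:
    errs = []
    for train_idx, test_idx in folds:
        model = svr_train(X[train_idx], y[train_idx], spec, C, epsilon, max_iter=60)
        pred = svr_predict(model, X[test_idx])
        errs.append(np.mean((pred - y[test_idx]) ** 2))
    return float(np.mean(errs))


def _make_folds(m: int, n_folds: int, seed: int):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    return [
        (np.setdiff1d(perm, part, assume_unique=True), part)
        for part in np.array_split(perm, n_folds)
    ]


def select_hyperparameters(
    X,
    y,
    kind: Kernel,
    C_grid: Optional[Sequence[float]] = None,
    epsilon_grid: Optional[Sequence[float]] = None,
    gamma_grid: Optional[Sequence[float]] = None,
    n_folds: int = 5,
    seed: int = 0,
    refine: bool = True,
) -> tuple[float, float, Optional[float]]:
    """Choose (C, epsilon, gamma) by seeded k-fold cross-validation.

    A log-spaced grid is searched exhaustively (defaults: C in 10^-2..10^4,
    eps in {0} plus 10^-4..10^-1 times std(y), gamma in 10^-4..10^2 divided
    by the input dimension), then C and gamma are locally refined by
    Nelder-Mead around the grid optimum.  Deterministic for a fixed seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    m, d = X.shape
    if m < 10:
        raise InvalidInputError("hyperparameter selection needs at least 10 points")
    sy = float(np.std(y)) or 1.0
    if C_grid is None:
        C_grid = np.logspace(-2, 4, 7)
    if epsilon_grid is None:
        epsilon_grid = np.concatenate([[0.0], np.logspace(-4, -1, 4) * sy])
    if kind is Kernel.LINEAR:
        gamma_grid = [None]
    elif gamma_grid is None:
        gamma_grid = np.logspace(-4, 2, 7) / d

    folds = _make_folds(m, n_folds, seed)
    best = (math.inf, None)
    for gamma in gamma_grid:
        spec = KernelSpec(kind, gamma)
        for C in C_grid:
            for eps in epsilon_grid:
                score = _cv_mse(X, y, spec, C, eps, folds)
                if score < best[0]:
                    best = (score, (float(C), float(eps), gamma))
    assert best[1] is not None
    C0, eps0, gamma0 = best[1]

    if refine:
        if kind is Kernel.RBF:
            def fun(z):
                return _cv_mse(X, y, KernelSpec(kind, 10.0 ** z[1]), 10.0 ** z[0], eps0, folds)
            z0 = [math.log10(C0), math.log10(gamma0)]
        else:
            def fun(z):
                return _cv_mse(X, y, KernelSpec(kind), 10.0 ** z[0], eps0, folds)
            z0 = [math.log10(C0)]
        res = scipy.optimize.minimize(
            fun, z0, method="Nelder-Mead",
            options={"maxfev": 25, "xatol": 0.05, "fatol": 1e-12},
        )
        if res.fun <= best[0]:
            C0 = 10.0 ** res.x[0]
            if kind is Kernel.RBF:
                gamma0 = 10.0 ** res.x[1]
    return C0, eps0, gamma0
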