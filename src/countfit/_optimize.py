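"""Shared numerical machinery: design scaling, quasi-Newton driver, Hessians.

All likelihoods are maximized on centered/scaled copies of the design
matrices (intercept untouched), which keeps L-BFGS well conditioned even
with raw-year age and age-squared regressors.  The scaling map is linear,
so coefficients and their covariance transform back exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize


@dataclass
class FitSettings:
    """Optimizer configuration shared by every family.

    tol is the relative log-likelihood convergence tolerance; restarts and
    seed only matter for the latent-class EM (number of random restarts and
    the seed of their perturbations).
    """

    tol: float = 1e-8
    maxiter: int = 500
    restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.maxiter < 1 or self.restarts < 0:
            raise ValueError("maxiter must be >= 1 and restarts >= 0")


@dataclass
class OptResult:
    theta: np.ndarray
    nll: float
    success: bool
    nit: int
    message: str = ""


class DesignScaler:
    """Center and scale non-constant columns of a design matrix.

    Column 0 must be the intercept.  ``coef_to_natural`` is the (exact,
    linear) map from coefficients in the scaled basis back to the original
    one; its matrix is exposed for covariance transforms.
    """

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        constant = self.scale_ < 1e-12
        self.mean_[constant] = 0.0
        self.scale_[constant] = 1.0
        p = X.shape[1]
        A = np.diag(1.0 / self.scale_)
        A[0, :] = -self.mean_ / self.scale_
        A[0, 0] = 1.0
        self.matrix_ = A  # beta_natural = A @ beta_scaled
        self.p = p

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def coef_to_natural(self, beta_scaled: np.ndarray) -> np.ndarray:
        return self.matrix_ @ np.asarray(beta_scaled, dtype=float)

    def coef_to_scaled(self, beta_natural: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.matrix_, np.asarray(beta_natural, dtype=float))


def minimize_nll(fun, theta0, settings: FitSettings, jac: bool = True,
                 gtol: float = 1e-6) -> OptResult:
    """L-BFGS-B driver for a (nll, grad) objective in unconstrained space."""
    theta0 = np.asarray(theta0, dtype=float)
    res = minimize(
        fun,
        theta0,
        jac=True if jac else None,
        method="L-BFGS-B",
        options={
            "maxiter": settings.maxiter,
            "maxfun": max(20 * settings.maxiter, 15000),
            "ftol": settings.tol,
            "gtol": gtol,
        },
    )
    nll = float(res.fun)
    success = bool(res.success) and np.isfinite(nll)
    return OptResult(np.asarray(res.x, dtype=float), nll, success, int(res.nit), str(res.message))


def hessian_from_grad(grad, theta, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient function."""
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    H = np.empty((p, p))
    for k in range(p):
        h = rel_step * (1.0 + abs(theta[k]))
        tp = theta.copy()
        tm = theta.copy()
        tp[k] += h
        tm[k] -= h
        H[:, k] = (grad(tp) - grad(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def hessian_from_fun(fun, theta, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian from a scalar function (no gradient)."""
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    h = rel_step * (1.0 + np.abs(theta))
    H = np.empty((p, p))
    f0 = fun(theta)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = fun(theta + 2 * ei)
        fmm = fun(theta - 2 * ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (4.0 * h[i] ** 2)
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            fa = fun(theta + ei + ej)
            fb = fun(theta + ei - ej)
            fc = fun(theta - ei + ej)
            fd = fun(theta - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd) / (4.0 * h[i] * h[j])
    return H


def cov_from_hessian(H: np.ndarray) -> np.ndarray:
    """Invert an observed-information matrix, falling back to a pseudo-inverse."""
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return cov
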