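"""Maximum-likelihood core for NB regression with modeled dispersion.

The canonical NB parameterization is used throughout: for mean ``mu`` and
dispersion ``phi``, ``Var = mu + phi * mu**2`` and the size parameter is
``1/phi``.  Both submodels use a log link; the mean submodel carries a
per-sample offset (log effective library size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import digamma, gammaln

__all__ = ["NBDoubleFit", "nb_loglik", "fit_nb_double_regression", "moment_dispersion"]

LOG_PHI_MIN = np.log(1e-8)
LOG_PHI_MAX = np.log(1e4)
GRAD_TOL = 1e-8
N_RESTARTS = 2


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> float:
    """Canonical NB log-likelihood with Var = mu + phi*mu**2."""
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def moment_dispersion(y: np.ndarray, floor: float = 1e-4) -> float:
    """Method-of-moments dispersion estimate, floored away from zero."""
    m = float(np.mean(y))
    if m <= 0:
        return floor
    v = float(np.var(y, ddof=1)) if y.size > 1 else m
    return max((v - m) / m**2, floor)


def _negloglik_and_grad(
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    offset: np.ndarray,
) -> tuple[float, np.ndarray]:
    k = X.shape[1]
    beta, gamma = params[:k], params[k:]
    eta_mu = np.clip(X @ beta + offset, -30.0, 30.0)
    eta_phi = np.clip(Z @ gamma, LOG_PHI_MIN, LOG_PHI_MAX)
    mu = np.exp(eta_mu)
    phi = np.exp(eta_phi)
    r = 1.0 / phi
    nll = -(
        np.sum(
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )
    # d ll / d eta_mu and d ll / d eta_phi, per observation
    d_mu = y - mu * (y + r) / (mu + r)
    d_r = digamma(y + r) - digamma(r) + np.log(r / (r + mu)) + 1.0 - (y + r) / (r + mu)
    d_phi = -r * d_r
    grad = -np.concatenate([X.T @ d_mu, Z.T @ d_phi])
    return float(nll), grad


@dataclass
class NBDoubleFit:
    """Result of one NB double-regression fit."""

    coef_mean: np.ndarray
    coef_disp: np.ndarray
    loglik: float
    se_mean: np.ndarray
    se_disp: np.ndarray
    converged: bool
    cov: np.ndarray = None

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.coef_mean, self.coef_disp])


def _numeric_hessian(fun, x0: np.ndarray, args: tuple, eps: float = 1e-5) -> np.ndarray:
    """Hessian from central differences of the analytic gradient."""
    n = x0.size
    H = np.empty((n, n))
    for i in range(n):
        step = eps * max(1.0, abs(x0[i]))
        xp, xm = x0.copy(), x0.copy()
        xp[i] += step
        xm[i] -= step
        H[:, i] = (fun(xp, *args)[1] - fun(xm, *args)[1]) / (2 * step)
    return 0.5 * (H + H.T)


def fit_nb_double_regression(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    offset: np.ndarray | None = None,
    start: np.ndarray | None = None,
) -> NBDoubleFit:
    """Fit log-linear submodels for the NB mean (with offset) and dispersion.

    Restarts from perturbed initial values when the quasi-Newton search
    fails; a fit that still has a large gradient afterwards is returned with
    ``converged=False`` (never raised).
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("y must contain non-negative integers")
    X = np.atleast_2d(X)
    Z = np.atleast_2d(Z)
    if offset is None:
        offset = np.zeros(y.size)
    offset = np.asarray(offset, dtype=float)

    if start is None:
        beta0 = np.zeros(X.shape[1])
        beta0[0] = np.log(max(np.mean(y / np.exp(offset)), 1e-8))
        gamma0 = np.zeros(Z.shape[1])
        gamma0[0] = np.log(moment_dispersion(y / np.exp(offset - np.mean(offset))))
        start = np.concatenate([beta0, gamma0])

    best = None
    rng = np.random.default_rng(12345)
    for attempt in range(1 + N_RESTARTS):
        x0 = start if attempt == 0 else start + rng.normal(0, 0.5, size=start.size)
        res = optimize.minimize(
            _negloglik_and_grad,
            x0,
            args=(y, X, Z, offset),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "gtol": GRAD_TOL, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success and np.max(np.abs(best.jac)) < 1e-3:
            break

    params = best.x
    k = X.shape[1]
    converged = bool(np.isfinite(best.fun)) and np.max(np.abs(best.jac)) < 1e-2
    H = _numeric_hessian(_negloglik_and_grad, params, (y, X, Z, offset))
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov).copy()
        if (diag <= 0).any():
            raise np.linalg.LinAlgError
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        cov = np.full((params.size, params.size), np.nan)
        se = np.full(params.size, np.nan)
    return NBDoubleFit(
        coef_mean=params[:k],
        coef_disp=params[k:],
        loglik=-float(best.fun),
        se_mean=se[:k],
        se_disp=se[k:],
        converged=converged,
        cov=cov,
    )
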