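"""Restricted maximum likelihood for small mixed models with independent random effects.

The trial models used here all have the form

    y = X beta + sum_i Z_i u_i + e,   u_i ~ N(0, sigma2_e * lambda_i * I),
    e ~ N(0, sigma2_e * W^{-1})

with one or two grouping factors (block, population) and optional known
per-record weights ``w`` (residual precision multipliers).  The residual
variance is profiled out analytically and the variance ratios ``lambda_i``
are found by optimising the restricted likelihood on the log scale: Brent
for a single ratio, Nelder-Mead for two.  Dense algebra is used throughout;
the trials this package analyses have at most a few hundred records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

_LOG_RATIO_BOUNDS = (-12.0, 12.0)
_RATIO_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Raised when the variance-ratio optimisation fails."""


@dataclass
class REMLFit:
    """Result of a restricted-maximum-likelihood fit."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_error: float
    ratios: dict[str, float]
    components: dict[str, float]
    blups: dict[str, np.ndarray] = field(default_factory=dict)
    reml_loglik: float = np.nan
    n_obs: int = 0


def _neg2_restricted_ll(log_ratios, y, X, Z_list, Winv_diag):
    n, p = y.shape[0], X.shape[1]
    V = np.diag(Winv_diag.copy())
    for lr, Z in zip(log_ratios, Z_list):
        lam = np.exp(lr)
        V += lam * (Z @ Z.T)
    try:
        c, low = linalg.cho_factor(V, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, None
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vinv_y = linalg.cho_solve((c, low), y, check_finite=False)
    if p > 0:
        Vinv_X = linalg.cho_solve((c, low), X, check_finite=False)
        XtVinvX = X.T @ Vinv_X
        try:
            cx, lowx = linalg.cho_factor(XtVinvX, check_finite=False)
        except linalg.LinAlgError:
            return np.inf, None
        logdet_X = 2.0 * np.sum(np.log(np.diag(cx)))
        beta = linalg.cho_solve((cx, lowx), X.T @ Vinv_y, check_finite=False)
        resid_quad = float(y @ Vinv_y - (X.T @ Vinv_y) @ beta)
    else:
        logdet_X = 0.0
        beta = np.zeros(0)
        resid_quad = float(y @ Vinv_y)
    dof = n - p
    # Guard the noise-free limit: the profile variance can underflow to zero.
    sigma2 = max(resid_quad / dof, 1e-300)
    n2ll = dof * np.log(sigma2) + logdet_V + logdet_X + dof
    return n2ll, (beta, sigma2, (c, low))


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    random_effects: dict[str, np.ndarray],
    weights: np.ndarray | None = None,
    tol: float = _RATIO_TOL,
) -> REMLFit:
    """Fit the mixed model by REML, profiling the residual variance.

    Parameters
    ----------
    y : response vector, length n.
    X : fixed-effect design (n, p); p may be zero (no fixed effects, in which
        case the restricted likelihood coincides with the full likelihood).
    random_effects : mapping of name -> indicator/design matrix (n, q_i).
    weights : optional per-record residual precision multipliers (> 0).

    Returns a :class:`REMLFit` with GLS fixed-effect estimates, their
    covariance, variance components on the data scale, and BLUPs of every
    random effect.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    names = list(random_effects)
    Z_list = [np.asarray(random_effects[k], dtype=float) for k in names]
    if weights is None:
        Winv_diag = np.ones(n)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("weights must be strictly positive")
        Winv_diag = 1.0 / weights

    def objective(log_ratios):
        val, _ = _neg2_restricted_ll(np.atleast_1d(log_ratios), y, X, Z_list, Winv_diag)
        return val

    lo, hi = _LOG_RATIO_BOUNDS
    if len(Z_list) == 0:
        best = np.zeros(0)
    elif len(Z_list) == 1:
        res = optimize.minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": tol}
        )
        if not res.success:
            raise ConvergenceError(f"variance-ratio optimisation failed: {res}")
        best = np.array([res.x])
    else:
        starts = [np.zeros(len(Z_list)), np.full(len(Z_list), -4.0)]
        best_res = None
        for x0 in starts:
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 2000},
            )
            if best_res is None or res.fun < best_res.fun:
                best_res = res
        if best_res is None or not np.isfinite(best_res.fun):
            raise ConvergenceError(f"variance-ratio optimisation failed: {best_res}")
        best = np.clip(best_res.x, lo, hi)

    n2ll, parts = _neg2_restricted_ll(best, y, X, Z_list, Winv_diag)
    if parts is None:
        raise ConvergenceError("restricted likelihood not finite at optimum")
    beta, sigma2, chol = parts
    ratios = {k: float(np.exp(b)) for k, b in zip(names, best)}
    # Ratios driven to the lower bound are numerically zero variance.
    for k in ratios:
        if ratios[k] <= np.exp(lo) * 1.01:
            ratios[k] = 0.0
    components = {k: sigma2 * r for k, r in ratios.items()}

    p = X.shape[1]
    if p > 0:
        Vinv_X = linalg.cho_solve(chol, X, check_finite=False)
        cov_beta = sigma2 * np.linalg.inv(X.T @ Vinv_X)
    else:
        cov_beta = np.zeros((0, 0))
    resid = y - (X @ beta if p else 0.0)
    Vinv_resid = linalg.cho_solve(chol, resid, check_finite=False)
    blups = {}
    for k, Z, lr in zip(names, Z_list, best):
        lam = ratios[k]
        blups[k] = lam * (Z.T @ Vinv_resid)
    return REMLFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2_error=float(sigma2),
        ratios=ratios,
        components=components,
        blups=blups,
        reml_loglik=-0.5 * n2ll,
        n_obs=n,
    )
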