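"""Direct maximum-likelihood Gaussian linear mixed models.

Fits models of the form

    y_i = X_i beta + Z_i b_i + e_i,     b_i ~ N(0, Psi),
    e_i ~ N(0, sigma^2 * diag(delta_{s(i)}^2))

for independent groups i (one random-effects level), with an optional
residual variance ratio ``delta_s`` per stratum (the first stratum is the
reference, delta_1 = 1).  The likelihood is profiled over ``beta`` and
``sigma^2``; the remaining parameters — the log-Cholesky factor of the
*relative* covariance ``Gamma = Psi / sigma^2`` and the log variance
ratios — are optimised by quasi-Newton iteration.  Only ML (not REML) is
provided, so nested fits support likelihood-ratio tests across both fixed
and random structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import solve_triangular

__all__ = ["LMMFit", "fit_lmm", "FitError"]


class FitError(RuntimeError):
    """Optimizer failed to produce a usable maximum-likelihood fit."""


@dataclass
class LMMFit:
    """Maximum-likelihood fit of a Gaussian linear mixed model.

    Attributes
    ----------
    beta : ndarray
        Fixed-effect estimates (GLS at the ML variance parameters).
    cov_beta : ndarray
        Model-based covariance of ``beta``.
    sigma2 : float
        Residual variance of the reference stratum.
    psi : ndarray or None
        Random-effect covariance matrix ``Psi`` (None when no random
        effects are present).
    stratum_sd : dict
        Residual SD per stratum.
    loglik : float
        Maximised log-likelihood.
    n_params : int
        Free parameters: fixed effects + variance parameters (incl.
        sigma^2).
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    psi: np.ndarray | None
    stratum_sd: dict
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    theta: np.ndarray

    def wald_t(self, j: int) -> float:
        return float(self.beta[j] / np.sqrt(self.cov_beta[j, j]))


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    """Lower-triangular Cholesky factor with log-parametrised diagonal."""
    L = np.zeros((q, q))
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[idx])
            else:
                L[i, j] = theta[idx]
            idx += 1
    return L


def _profiled_nll(theta, y_g, X_g, Z_g, strat_g, q, n_strata):
    """Negative profiled log-likelihood (beta and sigma^2 concentrated out).

    Returns (nll, beta, sigma2, XtVinvX) or (inf, ...) on failure.
    """
    n_chol = q * (q + 1) // 2
    L = _chol_from_theta(theta[:n_chol], q) if q else None
    delta2 = np.ones(n_strata)
    if n_strata > 1:
        delta2[1:] = np.exp(2.0 * theta[n_chol:])
    G = L @ L.T if q else None

    N = sum(len(y) for y in y_g)
    p = X_g[0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for y, X, Z, st in zip(y_g, X_g, Z_g, strat_g):
        n = len(y)
        D = delta2[st]
        if Z is None or q == 0:
            V0 = np.diag(D)
        else:
            V0 = Z @ G @ Z.T + np.diag(D)
        try:
            C = np.linalg.cholesky(V0)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        logdet += 2.0 * np.sum(np.log(np.diag(C)))
        Xw = solve_triangular(C, X, lower=True)
        yw = solve_triangular(C, y, lower=True)
        XtVX += Xw.T @ Xw
        XtVy += Xw.T @ yw
        yty += yw @ yw
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    rss = yty - 2.0 * beta @ XtVy + beta @ XtVX @ beta
    rss = max(rss, 1e-300)
    sigma2 = rss / N
    nll = 0.5 * (N * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)
    return nll, beta, sigma2, XtVX


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    re_design: np.ndarray | None = None,
    var_groups: np.ndarray | None = None,
    theta0: np.ndarray | None = None,
) -> LMMFit:
    """Fit a Gaussian LMM by direct maximum likelihood.

    Parameters
    ----------
    y, X : response vector and fixed-effects design matrix.
    groups : group label per observation (random-effects level).
    re_design : per-observation random-effects design (columns are the
        within-group effects), or None for a model without random effects.
    var_groups : stratum label per observation for heteroscedastic
        residual variances (None = one common variance).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("y and X have incompatible shapes")

    q = 0 if re_design is None else re_design.shape[1]
    if var_groups is None:
        strata = np.zeros(y.size, dtype=int)
        n_strata = 1
    else:
        labels, strata = np.unique(np.asarray(var_groups), return_inverse=True)
        n_strata = len(labels)

    glabels, ginv = np.unique(groups, return_inverse=True)
    y_g, X_g, Z_g, s_g = [], [], [], []
    for gi in range(len(glabels)):
        m = ginv == gi
        y_g.append(y[m])
        X_g.append(X[m])
        Z_g.append(None if re_design is None else np.asarray(re_design, float)[m])
        s_g.append(strata[m])

    n_chol = q * (q + 1) // 2
    n_theta = n_chol + (n_strata - 1)
    p = X.shape[1]

    if n_theta == 0:
        # plain (weighted-trivial) least squares: closed form
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        N = y.size
        sigma2 = float(resid @ resid) / N
        ll = -0.5 * N * (np.log(2.0 * np.pi * sigma2) + 1.0)
        XtX = X.T @ X
        return LMMFit(
            beta=beta,
            cov_beta=sigma2 * np.linalg.inv(XtX),
            sigma2=sigma2,
            psi=None,
            stratum_sd={0: float(np.sqrt(sigma2))},
            loglik=float(ll),
            n_params=p + 1,
            n_obs=N,
            converged=True,
            theta=np.empty(0),
        )

    if theta0 is None:
        theta0 = np.zeros(n_theta)
        # start diagonal Cholesky log-entries at 0 (Gamma = I), off-diag 0
    obj = lambda th: _profiled_nll(th, y_g, X_g, Z_g, s_g, q, n_strata)[0]

    bounds = []
    idx = 0
    for i in range(q):
        for j in range(i + 1):
            bounds.append((-10.0, 10.0) if i == j else (-50.0, 50.0))
            idx += 1
    bounds.extend([(-8.0, 8.0)] * (n_strata - 1))

    res = optimize.minimize(obj, theta0, method="L-BFGS-B", bounds=bounds)
    best = res
    # polish with a simplex pass; keeps the fit robust near variance bounds
    res2 = optimize.minimize(obj, best.x, method="Nelder-Mead",
                             options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    if res2.fun < best.fun:
        best = res2
    nll, beta, sigma2, XtVX = _profiled_nll(best.x, y_g, X_g, Z_g, s_g, q, n_strata)
    if not np.isfinite(nll) or beta is None:
        raise FitError("mixed-model likelihood optimisation failed")

    L = _chol_from_theta(best.x[:n_chol], q) if q else None
    psi = sigma2 * (L @ L.T) if q else None
    delta = np.ones(n_strata)
    if n_strata > 1:
        delta[1:] = np.exp(best.x[n_chol:])
    if var_groups is None:
        sds = {0: float(np.sqrt(sigma2))}
    else:
        sds = {lab: float(np.sqrt(sigma2) * delta[i]) for i, lab in enumerate(labels)}
    return LMMFit(
        beta=beta,
        cov_beta=sigma2 * np.linalg.inv(XtVX),
        sigma2=float(sigma2),
        psi=psi,
        stratum_sd=sds,
        loglik=float(-nll),
        n_params=p + n_theta + 1,
        n_obs=y.size,
        converged=bool(best.success or res2.fun <= res.fun + 1e-8),
        theta=best.x.copy(),
    )
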