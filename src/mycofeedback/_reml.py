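"""Restricted maximum likelihood engine for linear mixed models.

Fits y = X beta + sum_k u_k with marginal covariance

    V(theta) = V0 + sum_k sigma2_k A_k  (+ sigma2_e I when the residual
                                          variance is estimated)

where each A_k = Z_k G_k Z_k^T is a known n x n PSD structure matrix
(e.g. the phylogenetic covariance expanded to samples) and V0 is an
optional fixed covariance (the known sampling variances of a
meta-analysis).  Optimisation is a bounded quasi-Newton search on
log-variances with analytic gradients and multiple starts; beta is the
GLS solution at the optimum.

This is the one place variance components are estimated; both the
phylogenetic mixed model and the random-effects meta-regression call it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["RemlResult", "reml_fit", "reml_loglik"]

_LOG_FLOOR = -30.0  # exp(-30) ~ 1e-13: effectively a zero component


@dataclass
class RemlResult:
    """Converged (or flagged) REML fit."""

    sigma2: dict  # component name -> variance estimate
    beta: np.ndarray
    se_beta: np.ndarray
    cov_beta: np.ndarray
    loglik: float  # restricted log-likelihood (up to an additive constant)
    converged: bool
    grad_norm: float
    n_iter: int
    names: list = field(default_factory=list)  # fixed-effect column names

    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se_beta


def _build_V(theta, structures, V0, n, estimate_resid):
    V = np.zeros((n, n)) if V0 is None else V0.copy()
    k = 0
    for _, A in structures:
        V += np.exp(theta[k]) * A
        k += 1
    if estimate_resid:
        V[np.diag_indices_from(V)] += np.exp(theta[k])
    return V


def reml_loglik(theta, y, X, structures, V0=None, estimate_resid=True):
    """Restricted log-likelihood at log-variances ``theta`` (additive
    constants dropped). Returns -inf for numerically singular V."""
    n = len(y)
    V = _build_V(theta, structures, V0, n, estimate_resid)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    Vi_y = np.linalg.solve(V, y)
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = r @ np.linalg.solve(V, r)
    return -0.5 * (logdetV + logdetX + quad)


def _negloglik_and_grad(theta, y, X, structures, V0, estimate_resid):
    n = len(y)
    V = _build_V(theta, structures, V0, n, estimate_resid)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf, np.zeros_like(theta)
    Vinv = np.linalg.inv(V)
    Vi_X = Vinv @ X
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return np.inf, np.zeros_like(theta)
    XtViX_inv = np.linalg.inv(XtViX)
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    # REML projection P = Vinv - Vi_X (X' Vinv X)^-1 Vi_X'
    P = Vinv - Vi_X @ XtViX_inv @ Vi_X.T
    Py = P @ y
    quad = y @ Py
    nll = 0.5 * (logdetV + logdetX + quad)

    mats = [A for _, A in structures]
    if estimate_resid:
        mats = mats + [None]  # identity
    grad = np.empty(len(mats))
    for k, A in enumerate(mats):
        if A is None:
            PA_tr = np.trace(P)
            yPAPy = Py @ Py
        else:
            PA_tr = np.sum(P * A.T)
            APy = A @ Py
            yPAPy = Py @ APy
        # d nll / d theta_k, chain rule through sigma2_k = exp(theta_k)
        grad[k] = 0.5 * np.exp(theta[k]) * (PA_tr - yPAPy)
    return nll, grad


def reml_fit(
    y,
    X,
    structures,
    V0=None,
    estimate_resid=True,
    n_restarts=3,
    tol=1e-8,
    seed=0,
    beta_names=None,
):
    """REML fit of a linear mixed model with known covariance structures.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design, full column rank
    structures : list of (name, A) pairs, A an n x n PSD matrix
    V0 : optional fixed (n, n) covariance added to V (known sampling
        variances); when given with ``estimate_resid=False`` the model has
        no free residual term.
    estimate_resid : include an i.i.d. residual component sigma2_e I.
    n_restarts : additional randomised starts beyond the moment start.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible shapes")
    if n <= p:
        raise ValueError("need more samples than fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")

    k_est = len(structures) + (1 if estimate_resid else 0)
    if k_est == 0:
        raise ValueError("no variance components to estimate")

    vy = max(np.var(y), 1e-12)
    rng = np.random.default_rng(seed)
    starts = [np.full(k_est, np.log(vy / k_est))]
    for _ in range(n_restarts):
        starts.append(np.log(vy) + rng.uniform(-4.0, 1.0, size=k_est))

    bounds = [(_LOG_FLOOR, np.log(vy) + 8.0)] * k_est
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _negloglik_and_grad,
            x0,
            args=(y, X, structures, V0, estimate_resid),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-6, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    V = _build_V(theta, structures, V0, n, estimate_resid)
    Vinv = np.linalg.inv(V)
    XtViX = X.T @ Vinv @ X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (X.T @ (Vinv @ y))
    se = np.sqrt(np.diag(cov_beta))

    sigma2 = {name: float(np.exp(t)) for (name, _), t in zip(structures, theta)}
    # components driven to the boundary are reported as exact zeros
    sigma2 = {k: (0.0 if np.log(max(v, 1e-300)) <= _LOG_FLOOR + 1e-6 else v)
              for k, v in sigma2.items()}
    if estimate_resid:
        sigma2["resid"] = float(np.exp(theta[-1]))

    grad_norm = float(np.linalg.norm(best.jac))
    # at a boundary minimum the gradient can legitimately point outward
    interior = theta > _LOG_FLOOR + 1e-6
    g_int = float(np.linalg.norm(best.jac[interior])) if interior.any() else 0.0
    converged = bool(best.success) and g_int < 1e-3 * max(1.0, abs(best.fun))

    return RemlResult(
        sigma2=sigma2,
        beta=beta,
        se_beta=se,
        cov_beta=cov_beta,
        loglik=-float(best.fun),
        converged=converged,
        grad_norm=grad_norm,
        n_iter=int(best.nit),
        names=list(beta_names) if beta_names is not None else [],
    )
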