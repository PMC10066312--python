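"""Random-intercept logistic mixed model via Gauss-Hermite quadrature.

Fits  logit P(y_ij = 1) = x_ij' beta + u_i,  u_i ~ N(0, tau^2)
by maximizing the marginal likelihood, integrating the participant
intercepts with Gauss-Hermite quadrature (21 nodes by default; the
integrand is a product of at most a few dozen Bernoulli terms per
participant, for which fixed-node GH is accurate at the tau values seen
here).  Standard errors come from the numerical Hessian of the negative
log-likelihood at the optimum, p-values from Wald z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm


class ConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood optimization fails."""


@dataclass
class GLMMResult:
    names: list[str]
    beta: np.ndarray          # fixed effects (log-odds)
    se: np.ndarray
    tau: float                # random-intercept SD
    vcov: np.ndarray          # fixed-effect covariance block
    loglik: float
    converged: bool
    separation: bool          # any |beta| implausibly large

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.z))

    def coef_table(self) -> pd.DataFrame:
        ci = 1.959963984540054 * self.se
        return pd.DataFrame(dict(
            term=self.names, b=self.beta, se=self.se, z=self.z, p=self.p,
            ci_low=self.beta - ci, ci_high=self.beta + ci,
        ))


def _nll_factory(X, y, group_idx, n_groups, nodes, weights):
    """Negative marginal log-likelihood (up to binomial constants).

    Bernoulli rows are collapsed to binomial sufficient statistics per
    (participant, distinct design row), which leaves the likelihood shape
    unchanged while shrinking the quadrature workload by the trial count
    per cell.
    """
    logw = np.log(weights / np.sqrt(np.pi))
    stacked = np.column_stack([group_idx.astype(float)[:, None], X])
    uniq, inv = np.unique(stacked, axis=0, return_inverse=True)
    k = np.bincount(inv, weights=y, minlength=len(uniq))
    n = np.bincount(inv, minlength=len(uniq)).astype(float)
    Xa = uniq[:, 1:]
    ga = uniq[:, 0].astype(int)

    def nll(params):
        beta, log_tau = params[:-1], params[-1]
        tau = np.exp(log_tau)
        eta0 = Xa @ beta
        u = np.sqrt(2.0) * tau * nodes            # (K,)
        eta = eta0[:, None] + u[None, :]          # (M, K)
        # binomial loglik: k*eta - n*log(1 + e^eta), stable via logaddexp
        ll = k[:, None] * eta - n[:, None] * np.logaddexp(0.0, eta)
        S = np.zeros((n_groups, ll.shape[1]))
        np.add.at(S, ga, ll)
        return -float(np.sum(logsumexp(S + logw[None, :], axis=1)))

    return nll


def _logistic_start(X, y, max_iter=50):
    """Plain logistic regression by Newton-Raphson for starting values."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1 - p) + 1e-9
        H = X.T @ (X * W[:, None]) + 1e-8 * np.eye(X.shape[1])
        step = np.linalg.solve(H, X.T @ (y - p))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _numerical_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def fit_logistic_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    n_quad: int = 21,
    tol: float = 1e-6,
) -> GLMMResult:
    """Fit the random-intercept logistic model.

    ``X`` is the fixed-effect design (including the intercept column),
    ``groups`` labels the random-intercept clusters (participants).
    Raises :class:`ConvergenceError` when the optimizer fails; flags
    likely complete separation instead of silently returning huge
    coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X and y shapes are inconsistent")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    uniq, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two participants")
    names = names or [f"x{i}" for i in range(X.shape[1])]

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    nll = _nll_factory(X, y, group_idx, len(uniq), nodes, weights)

    beta0 = _logistic_start(X, y)
    x0 = np.r_[beta0, np.log(0.5)]
    res = minimize(nll, x0, method="BFGS",
                   options=dict(gtol=tol * 10, maxiter=500))
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"marginal likelihood diverged: {res.message}")
    xhat = res.x
    H = _numerical_hessian(nll, xhat)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular Hessian at optimum: {exc}") from exc
    p = X.shape[1]
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    beta = xhat[:p]
    separation = bool(np.max(np.abs(beta)) > 15.0)
    return GLMMResult(
        names=list(names), beta=beta, se=se, tau=float(np.exp(xhat[-1])),
        vcov=cov[:p, :p], loglik=-float(res.fun),
        converged=bool(res.success or np.linalg.norm(res.jac) < 1e-2),
        separation=separation,
    )
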