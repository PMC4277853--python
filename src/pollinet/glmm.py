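"""Random-intercept logistic regression via adaptive Gauss-Hermite quadrature.

Model: y_ij ~ Bernoulli(logistic(x_ij . beta + b_i)), b_i ~ N(0, sigma^2),
one random intercept per group.  The marginal likelihood integrates b_i out
with adaptive quadrature (nodes recentred at each group's posterior mode and
rescaled by its curvature), the standard approach of lme4-style fitters.
Maximum likelihood over (beta, log sigma) with L-BFGS-B; Wald standard
errors from the numerical Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.special
import scipy.stats
from scipy.special import expit
from numpy.polynomial.hermite import hermgauss
from statsmodels.tools import numdiff

__all__ = ["GLMMResult", "fit_logistic_glmm"]

_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = -8.0, 5.0


@dataclass(frozen=True)
class GLMMResult:
    """Fitted random-intercept logistic model."""

    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    sigma: float
    sigma_se: float | None
    loglik: float
    cov: np.ndarray
    converged: bool
    n_obs: int
    n_groups: int

    def predict_logodds(self, X: np.ndarray) -> np.ndarray:
        """Fixed-effects linear predictor (random effect at 0)."""
        return np.asarray(X, dtype=float) @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.predict_logodds(X)))


class _Marginal:
    """Negative marginal log-likelihood with pre-sorted group blocks."""

    def __init__(self, X, y, groups, n_quad):
        order = np.argsort(groups, kind="stable")
        self.X = np.asarray(X, dtype=float)[order]
        self.y = np.asarray(y, dtype=float)[order]
        g = np.asarray(groups)[order]
        _, self.gidx, counts = np.unique(g, return_inverse=True, return_counts=True)
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.n_groups = len(counts)
        self.nodes, self.weights = hermgauss(n_quad)
        self.log_weights = np.log(self.weights) + self.nodes**2

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts, axis=0)

    def _posterior_modes(self, eta: np.ndarray, sigma2: float):
        """Newton iteration for each group's mode of loglik + log prior."""
        b = np.zeros(self.n_groups)
        for _ in range(100):
            lin = eta + b[self.gidx]
            p = expit(lin)
            score = self._group_sum(self.y - p) - b / sigma2
            info = self._group_sum(p * (1.0 - p)) + 1.0 / sigma2
            step = score / info
            b += np.clip(step, -5.0, 5.0)
            if np.max(np.abs(step)) < 1e-12:
                break
        lin = eta + b[self.gidx]
        p = expit(lin)
        curvature = self._group_sum(p * (1.0 - p)) + 1.0 / sigma2
        return b, 1.0 / np.sqrt(curvature)

    def nll(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        log_sigma = np.clip(log_sigma, _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
        sigma = np.exp(log_sigma)
        sigma2 = sigma * sigma
        eta = self.X @ beta
        mode, scale = self._posterior_modes(eta, sigma2)
        # adaptive nodes b_q = mode + sqrt(2) * scale * t_q
        b_q = mode[:, None] + np.sqrt(2.0) * scale[:, None] * self.nodes[None, :]
        lin = eta[:, None] + b_q[self.gidx]
        ll_obs = self.y[:, None] * lin - np.logaddexp(0.0, lin)
        ll_group = self._group_sum(ll_obs)  # (n_groups, n_quad)
        log_prior = (
            -0.5 * (b_q**2) / sigma2 - 0.5 * np.log(2.0 * np.pi) - log_sigma
        )
        log_terms = self.log_weights[None, :] + ll_group + log_prior
        ll = scipy.special.logsumexp(log_terms, axis=1) + 0.5 * np.log(2.0) + np.log(
            scale
        )
        return -float(ll.sum())


def fit_logistic_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 15,
    start: np.ndarray | None = None,
) -> GLMMResult:
    """Fit the random-intercept logistic model by maximum likelihood.

    Parameters
    ----------
    X
        (n_obs, n_fixed) design matrix including any intercept column.
    y
        Binary responses in {0, 1}.
    groups
        Group label per observation (the random-intercept factor).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("responses must be binary")
    marg = _Marginal(X, y, groups, n_quad)
    if marg.n_groups < 2:
        raise ValueError("random intercept needs >= 2 groups")

    if start is None:
        # pooled ridge-regularized logistic start (few Newton steps)
        beta0 = np.zeros(X.shape[1])
        for _ in range(25):
            p = expit(X @ beta0)
            w = np.maximum(p * (1.0 - p), 1e-6)
            H = X.T @ (X * w[:, None]) + 1e-6 * np.eye(X.shape[1])
            g = X.T @ (y - p) - 1e-6 * beta0
            beta0 += np.linalg.solve(H, g)
        start = np.concatenate([beta0, [np.log(0.5)]])

    opt = scipy.optimize.minimize(
        marg.nll,
        start,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)],
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    params = opt.x
    # explicit step: the objective carries O(1e-6) inner-loop noise, so
    # curvature needs h well above the default (h^2 must dominate the noise)
    cov_full = None
    for step in (5e-3, 2e-2, 5e-2):
        hess = numdiff.approx_hess2(params, marg.nll, epsilon=step)
        try:
            candidate = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            continue
        if np.all(np.diag(candidate) > 0):
            cov_full = candidate
            break
    if cov_full is None:
        cov_full = np.full((len(params), len(params)), np.nan)
    se_full = np.sqrt(np.abs(np.diag(cov_full)))

    k = X.shape[1]
    coef, se = params[:k], se_full[:k]
    zvals = coef / se
    pvals = 2.0 * scipy.stats.norm.sf(np.abs(zvals))
    sigma = float(np.exp(params[-1]))
    sigma_se = (
        float(se_full[-1] * sigma) if np.isfinite(se_full[-1]) else None
    )  # delta method from log scale
    return GLMMResult(
        coef=coef,
        se=se,
        zvalues=zvals,
        pvalues=pvals,
        sigma=sigma,
        sigma_se=sigma_se,
        loglik=-float(opt.fun),
        cov=cov_full[:k, :k],
        converged=bool(opt.success),
        n_obs=len(y),
        n_groups=marg.n_groups,
    )
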