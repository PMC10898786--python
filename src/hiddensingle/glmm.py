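"""Logistic mixed-effects regression via the Laplace approximation.

Supports rectangular grouped data (every group observes the same number of
trials), fixed-effect design matrices of any width, and independent
Gaussian random effects on up to a few within-group columns (intercept
and/or slope). The marginal likelihood integrates the random effects with
a per-group Laplace approximation around the posterior mode (found by
damped Newton); predictions plug in the empirical-Bayes modes. A weak
ridge prior (sd 10 on the logit scale) keeps fixed effects finite under
complete separation, e.g. error-free participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

RIDGE_VAR = 100.0  # prior variance of fixed effects on the logit scale
_MIN_LOG_SD, _MAX_LOG_SD = -6.0, 4.0


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    out = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30))))
    return out


@dataclass
class LogisticGLMMResult:
    beta: np.ndarray  # fixed effects
    beta_se: np.ndarray
    re_sd: np.ndarray  # random-effect standard deviations
    ranef: np.ndarray  # (n_groups, q) empirical-Bayes modes
    group_ids: list
    loglik: float
    converged: bool
    message: str = ""
    fixed_names: list = field(default_factory=list)

    def predict_logit(self, group, x_row: np.ndarray) -> float:
        """Conditional linear predictor for one group at fixed-design row x."""
        try:
            ix = self.group_ids.index(group)
        except ValueError:
            raise KeyError(f"unknown group id: {group!r}") from None
        x_row = np.asarray(x_row, dtype=float)
        # random-effect columns are the leading columns of the fixed design
        q = self.ranef.shape[1]
        return float(x_row @ self.beta + x_row[:q] @ self.ranef[ix])

    def predict_proba(self, group, x_row: np.ndarray) -> float:
        return float(_sigmoid(np.array([self.predict_logit(group, x_row)]))[0])


def _newton_modes(y, X, Z, beta, inv_var, b0, n_iter=50, tol=1e-10):
    """Per-group posterior modes of the random effects (vectorized Newton)."""
    n, T, q = Z.shape
    b = b0.copy()
    offset = X @ beta  # (n, T)
    for _ in range(n_iter):
        eta = offset + np.einsum("ntq,nq->nt", Z, b)
        mu = _sigmoid(eta)
        g = np.einsum("ntq,nt->nq", Z, y - mu) - b * inv_var
        w = mu * (1.0 - mu)
        H = np.einsum("nti,nt,ntj->nij", Z, w, Z) + np.eye(q) * inv_var
        step = np.linalg.solve(H, g[..., None])[..., 0]
        # damped update: halve steps until the penalized objective improves
        obj = _joint_obj(y, offset, Z, b, inv_var)
        scale = 1.0
        for _ in range(20):
            b_new = b + scale * step
            if _joint_obj(y, offset, Z, b_new, inv_var) >= obj - 1e-12:
                break
            scale *= 0.5
        b = b + scale * step
        if np.max(np.abs(scale * step)) < tol:
            break
    return b


def _joint_obj(y, offset, Z, b, inv_var):
    eta = offset + np.einsum("ntq,nq->nt", Z, b)
    ll = (y * eta - _log1pexp(eta)).sum()
    return ll - 0.5 * ((b**2) * inv_var).sum()


def _neg_marginal(theta, y, X, Z, p, q, warm_b):
    beta = theta[:p]
    log_sd = np.clip(theta[p:], _MIN_LOG_SD, _MAX_LOG_SD)
    var = np.exp(2.0 * log_sd)
    inv_var = 1.0 / var
    b = _newton_modes(y, X, Z, beta, inv_var, warm_b)
    warm_b[...] = b

    offset = X @ beta
    eta = offset + np.einsum("ntq,nq->nt", Z, b)
    mu = _sigmoid(eta)
    ll = (y * eta - _log1pexp(eta)).sum()
    quad = 0.5 * ((b**2) * inv_var).sum()
    w = mu * (1.0 - mu)
    H = np.einsum("nti,nt,ntj->nij", Z, w, Z) + np.eye(q) * inv_var
    sign, logdet_H = np.linalg.slogdet(H)
    logdet_D = 2.0 * log_sd.sum()  # per group
    n = y.shape[0]
    log_marginal = ll - quad - 0.5 * logdet_H.sum() - 0.5 * n * logdet_D
    ridge = 0.5 * (beta**2).sum() / RIDGE_VAR
    return -(log_marginal) + ridge


def fit_logistic_glmm(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    group_ids: list,
    fixed_names: list | None = None,
) -> LogisticGLMMResult:
    """Fit a logistic mixed model on rectangular grouped data.

    Parameters
    ----------
    y : (n_groups, T) binary outcomes
    X : (n_groups, T, p) fixed-effect design (column 0 should be 1s)
    Z : (n_groups, T, q) random-effect design per group
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, T = y.shape
    p, q = X.shape[2], Z.shape[2]
    if n < 2:
        raise ValueError("at least 2 groups are required")

    warm_b = np.zeros((n, q))
    theta0 = np.concatenate([np.zeros(p), np.zeros(q)])
    res = minimize(
        _neg_marginal,
        theta0,
        args=(y, X, Z, p, q, warm_b),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    beta = res.x[:p]
    log_sd = np.clip(res.x[p:], _MIN_LOG_SD, _MAX_LOG_SD)
    inv_var = np.exp(-2.0 * log_sd)
    ranef = _newton_modes(y, X, Z, beta, inv_var, warm_b)

    beta_se = _wald_se(res.x, y, X, Z, p, q, warm_b)[:p]
    return LogisticGLMMResult(
        beta=beta,
        beta_se=beta_se,
        re_sd=np.exp(log_sd),
        ranef=ranef,
        group_ids=list(group_ids),
        loglik=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        fixed_names=list(fixed_names or [f"x{j}" for j in range(p)]),
    )


def _wald_se(theta, y, X, Z, p, q, warm_b, h: float = 1e-3) -> np.ndarray:
    """Standard errors from a central-difference Hessian of the objective.

    Variance components pinned at their bounds leave flat directions, so the
    full Hessian can be singular; fall back to the fixed-effect block, whose
    curvature stays well-conditioned.
    """
    k = len(theta)
    hess = np.empty((k, k))
    cache: dict[tuple, float] = {}

    def f(t):
        key = tuple(np.round(t, 12))
        if key not in cache:
            cache[key] = _neg_marginal(t, y, X, Z, p, q, warm_b.copy())
        return cache[key]

    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            hess[i, j] = hess[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4.0 * h**2)

    se = np.full(k, np.nan)
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if np.all(np.isfinite(diag[:p])) and np.all(diag[:p] > 0):
            return np.sqrt(np.clip(diag, 0.0, None))
    except np.linalg.LinAlgError:
        pass
    try:
        cov_b = np.linalg.inv(hess[:p, :p])
        diag_b = np.diag(cov_b)
        if np.all(np.isfinite(diag_b)) and np.all(diag_b > 0):
            se[:p] = np.sqrt(diag_b)
    except np.linalg.LinAlgError:
        pass
    return se
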