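"""Slow reference solvers used only for validation.

These deliberately share no code with the production coordinate-descent
solver: the elastic-net objective is minimized by a generic bound-constrained
quasi-Newton method on the split formulation beta = u - v with u, v >= 0,
which turns the L1 term into a smooth linear one.  An unpenalized weighted
IRLS logistic fit is also provided.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["reference_en_logistic", "irls_logistic", "en_objective"]


def en_objective(X, y, w, b0, beta, lam, alpha) -> float:
    """Penalized weighted binomial deviance (the quantity both solvers
    minimize)."""
    eta = b0 + X @ beta
    ll = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30.0))))
    loss = np.sum(w * (ll - y * eta)) / y.size
    return float(
        loss + lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * beta @ beta)
    )


def reference_en_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    alpha: float,
    tol: float = 1e-12,
):
    """Generic convex-optimization solution of the elastic-net logistic
    objective (L-BFGS-B on the split-variable formulation)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    N, p = X.shape

    def fun(theta):
        b0 = theta[0]
        u, v = theta[1 : p + 1], theta[p + 1 :]
        beta = u - v
        eta = b0 + X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = np.where(eta > 30, eta, np.log1p(np.exp(np.minimum(eta, 30.0))))
        f = np.sum(w * (ll - y * eta)) / N + lam * (
            alpha * (u.sum() + v.sum()) + 0.5 * (1 - alpha) * beta @ beta
        )
        g_eta = w * (mu - y) / N
        g_beta = X.T @ g_eta
        gu = g_beta + lam * alpha + lam * (1 - alpha) * beta
        gv = -g_beta + lam * alpha - lam * (1 - alpha) * beta
        return f, np.concatenate([[g_eta.sum()], gu, gv])

    theta0 = np.zeros(2 * p + 1)
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    res = minimize(
        fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 5000, "ftol": tol, "gtol": 1e-10},
    )
    b0 = float(res.x[0])
    beta = res.x[1 : p + 1] - res.x[p + 1 :]
    return b0, beta, en_objective(X, y, w, b0, beta, lam, alpha)


def irls_logistic(
    X: np.ndarray, y: np.ndarray, w: np.ndarray,
    tol: float = 1e-12, max_iter: int = 200,
):
    """Unpenalized weighted logistic regression by plain Newton/IRLS."""
    X1 = np.column_stack([np.ones(y.size), X])
    theta = np.zeros(X1.shape[1])
    for _ in range(max_iter):
        eta = X1 @ theta
        mu = 1.0 / (1.0 + np.exp(-eta))
        v = np.clip(mu * (1 - mu), 1e-10, None)
        W = w * v
        grad = X1.T @ (w * (y - mu))
        H = (X1 * W[:, None]).T @ X1
        step = np.linalg.solve(H, grad)
        theta = theta + step
        if np.max(np.abs(step)) < tol:
            break
    return float(theta[0]), theta[1:]
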