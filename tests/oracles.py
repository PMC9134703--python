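"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they verify: the Cox oracle is a
hand-written Breslow partial likelihood maximised by brute force / Newton
steps, the OLS oracle solves the normal equations directly, and the BH
oracle is the textbook step-up computation.
"""

from __future__ import annotations

import numpy as np


def phs_loop(dosages: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-individual score via an explicit loop (no linear algebra)."""
    n, m = dosages.shape
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(m):
            s += weights[j] * dosages[i, j]
        out[i] = s
    return out


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """beta = (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def bh_by_hand(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up: sort, p(i)*m/i, cumulative minimum, cap at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def cox_neg_partial_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                           event: np.ndarray) -> float:
    """Negative Breslow partial log-likelihood (valid when times are untied)."""
    eta = X @ beta
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = time >= time[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return -ll


def cox_mle_grid(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                 lo: float = -5.0, hi: float = 5.0, tol: float = 1e-6) -> float:
    """1-covariate partial-likelihood maximiser by iterated grid refinement."""
    assert X.shape[1] == 1
    a, b = lo, hi
    while b - a > tol:
        grid = np.linspace(a, b, 41)
        vals = [cox_neg_partial_loglik(np.array([g]), X, time, event) for g in grid]
        k = int(np.argmin(vals))
        a, b = grid[max(k - 1, 0)], grid[min(k + 1, 40)]
    return 0.5 * (a + b)


def cox_mle_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   n_iter: int = 60) -> np.ndarray:
    """Multi-covariate partial-likelihood maximiser by finite-difference Newton."""
    from scipy.optimize import minimize

    res = minimize(
        cox_neg_partial_loglik,
        np.zeros(X.shape[1]),
        args=(X, time, event),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
    )
    return res.x


def km_empirical(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Empirical survival S(t) = P(T > t) (the KM limit with no censoring)."""
    return np.array([(times > t).mean() for t in grid])
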