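"""Independent brute-force oracles shared by the acceptance checks.

Each oracle recomputes a quantity by the most literal method available
(double/triple loops, exhaustive grids), deliberately avoiding the
vectorized implementation paths it is used to verify.
"""

import numpy as np


def brute_force_grm(X, alpha):
    """Double-loop MAF-weighted GRM."""
    n, m = X.shape
    p = X.mean(axis=0) / 2.0
    f = np.minimum(p, 1 - p)
    s = (2 * f * (1 - f)) ** alpha
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            for v in range(m):
                K[i, j] += s[v] * (X[i, v] - 2 * p[v]) * (X[j, v] - 2 * p[v])
    return K / (np.trace(K) / n)


def brute_force_tom(A):
    """Triple-loop topological overlap."""
    n = A.shape[0]
    Ad = A.copy()
    np.fill_diagonal(Ad, 0.0)
    k = Ad.sum(axis=1)
    T = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                T[i, j] = 1.0
                continue
            s = sum(Ad[i, u] * Ad[u, j] for u in range(n))
            T[i, j] = (s + Ad[i, j]) / (min(k[i], k[j]) + 1 - Ad[i, j])
    return T


def grid_profile_oracle(y, X, K, n_grid=20001):
    """Eigen-rotation restricted-likelihood grid search over h2."""
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0)
    yr, Xr = U.T @ y, U.T @ X
    n, p = X.shape
    best, best_ll = 0.0, -np.inf
    for h2 in np.linspace(0, 1 - 1e-6, n_grid):
        d = h2 * lam + (1 - h2)
        w = 1.0 / d
        XtWX = Xr.T @ (Xr * w[:, None])
        beta = np.linalg.solve(XtWX, Xr.T @ (yr * w))
        r = yr - Xr @ beta
        s2 = float(r @ (r * w)) / (n - p)
        ll = -0.5 * (np.sum(np.log(d)) + np.linalg.slogdet(XtWX)[1]
                     + (n - p) * np.log(s2) + (n - p))
        if ll > best_ll:
            best, best_ll = h2, ll
    return best
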