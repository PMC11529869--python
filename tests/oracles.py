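"""Independent brute-force oracles used by the test suite.

Everything here forms dense matrices and uses direct linear algebra
(explicit inverses, log-determinants, grid searches), deliberately avoiding
the streaming/eigendecomposition code paths of the package under test.
"""

from __future__ import annotations

import numpy as np


def normalize_dense(dosages: np.ndarray, maf_min: float = 0.01):
    """One-shot normalization oracle: impute to 2p, center, binomial scale.

    Returns (W, kept_indices, p).
    """
    g = np.asarray(dosages, dtype=float)
    g = np.where(g == -1, np.nan, g)
    p = np.nanmean(g, axis=0) / 2.0
    var = np.nanvar(g, axis=0)
    maf = np.minimum(p, 1.0 - p)
    kept = np.flatnonzero(np.isfinite(p) & (maf >= maf_min) & (var > 1e-12))
    gk = g[:, kept]
    pk = p[kept]
    gk = np.where(np.isnan(gk), 2.0 * pk, gk)
    W = (gk - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    return W, kept, pk


def dense_loglik(tau: float, K0: np.ndarray, m: int, y: np.ndarray, X: np.ndarray,
                 mode: str = "REML") -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood via dense solves and slogdet (no eigen trick).

    Returns (value, beta_hat, sigma_g2_hat).
    """
    s1 = len(y)
    H = K0 / m + tau * np.eye(s1)
    Hinv_y = np.linalg.solve(H, y)
    k = X.shape[1] if X.ndim == 2 else 0
    if k:
        Hinv_X = np.linalg.solve(H, X)
        A = X.T @ Hinv_X
        beta = np.linalg.solve(A, X.T @ Hinv_y)
        r = y - X @ beta
    else:
        beta = np.empty(0)
        r = y
    Q = float(r @ np.linalg.solve(H, r))
    dof = s1 if mode == "ML" else s1 - k
    sigma_g2 = Q / dof
    _, logdetH = np.linalg.slogdet(H)
    value = -0.5 * (dof * np.log(2.0 * np.pi * sigma_g2) + logdetH + dof)
    if mode == "REML" and k:
        _, logdetA = np.linalg.slogdet(A)
        value -= 0.5 * logdetA
    return value, beta, sigma_g2


def golden_max(f, lo: float, hi: float, tol: float = 1e-12, max_iter: int = 300):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (c, fc) if fc > fd else (d, fd)


def grid_golden_fit(K0: np.ndarray, m: int, y: np.ndarray, X: np.ndarray,
                    mode: str = "REML", n_grid: int = 10000):
    """Derivative-free variance-ratio fit: coarse grid, then golden polish.

    Returns (tau_hat, loglik, sigma_g2_hat).
    """
    thetas = np.linspace(np.log(1e-6), np.log(1e6), n_grid)

    def ll(theta):
        return dense_loglik(float(np.exp(theta)), K0, m, y, X, mode)[0]

    vals = np.array([ll(t) for t in thetas])
    i = int(np.argmax(vals))
    lo = thetas[max(i - 1, 0)]
    hi = thetas[min(i + 1, n_grid - 1)]
    theta, value = golden_max(ll, lo, hi)
    tau = float(np.exp(theta))
    _, _, sg2 = dense_loglik(tau, K0, m, y, X, mode)
    return tau, value, sg2


def brute_force_scan(W: np.ndarray, y: np.ndarray, X: np.ndarray, mode: str = "REML",
                     tau: float | None = None, sigma_g2: float | None = None):
    """Unsketched LMM scan: explicit V, dense inverse, GLS residualization.

    Variance components are fitted by grid + golden section unless supplied
    (supplying them isolates the scan machinery from optimizer tolerances).
    Returns (chisq, tau_hat, sigma_g2_hat).
    """
    n, m = W.shape
    K0 = W @ W.T
    if tau is None:
        tau, _, sg2 = grid_golden_fit(K0, m, y, X, mode)
    else:
        sg2 = sigma_g2
    V = sg2 * (K0 / m + tau * np.eye(n))
    Vinv = np.linalg.inv(V)
    k = X.shape[1] if X.ndim == 2 else 0
    if k:
        A = X.T @ Vinv @ X
        Py = y - X @ np.linalg.solve(A, X.T @ Vinv @ y)
        PZ = W - X @ np.linalg.solve(A, X.T @ Vinv @ W)
    else:
        Py, PZ = y, W
    num = PZ.T @ (Vinv @ Py)
    den = np.einsum("ij,ij->j", PZ, Vinv @ PZ)
    return num**2 / den, tau, sg2


def hudson_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Hudson's FST estimator from two pools of diploid dosages."""
    n1, n2 = len(g1), len(g2)
    p1 = g1.mean(axis=0) / 2.0
    p2 = g2.mean(axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())
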