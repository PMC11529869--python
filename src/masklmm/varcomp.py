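"""Variance-component estimation for the sketched mixed model.

The sketched response is modelled as

    y_s1 ~ N(X beta, sigma_g^2 * H_tau),    H_tau = (1/m) K + tau I,

with tau = sigma_e^2 / sigma_g^2 the ratio of residual to genetic variance
and heritability h^2 = 1 / (1 + tau).  One eigendecomposition K = U L U^T
makes H_tau diagonal in the rotated basis for every tau, so each likelihood
evaluation is O(s1 k^2).  beta and sigma_g^2 are profiled out analytically;
the remaining one-dimensional objective is maximized by Newton's method in
theta = log tau (positivity for free), with step halving and a
golden-section safeguard.

Writing D = diag(lambda_i / m + tau), y~ = U^T y_s1 and X~ = U^T X:

    beta^     = (X~' D^-1 X~)^-1 X~' D^-1 y~
    r         = y~ - X~ beta^
    sigma_g^2 = r' D^-1 r / s1           (ML; REML divides by s1 - k)
    l_ML      = -1/2 [ s1 log(2 pi sigma_g^2) + sum_i log D_i + s1 ]
    l_REML    = l with s1 -> s1 - k and an extra -1/2 log det(X~' D^-1 X~)

First and second derivatives in theta follow from d D_i / d tau = 1 and the
envelope theorem (beta^ is a stationary point of the quadratic form), so no
numerical differentiation is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("masklmm")

THETA_LO = np.log(1e-6)
THETA_HI = np.log(1e6)


@dataclass
class Spectrum:
    """Eigendecomposition of the sketched GRM K, plus the marker count m
    that scales it inside H_tau."""

    eigenvalues: np.ndarray  # descending, clipped at 0
    eigenvectors: np.ndarray  # columns orthonormal
    n_markers: int


@dataclass
class VarianceComponents:
    tau: float
    sigma_g2: float
    beta: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    mode: str = "ML"
    newton_converged: bool = True

    @property
    def sigma_e2(self) -> float:
        return self.tau * self.sigma_g2

    @property
    def h2(self) -> float:
        return 1.0 / (1.0 + self.tau)


def eigendecompose(K: np.ndarray, n_markers: int) -> Spectrum:
    """Symmetric eigendecomposition with negative eigenvalues clipped to 0."""
    K = np.asarray(K, dtype=float)
    if not np.all(np.isfinite(K)):
        raise ValueError("GRM contains non-finite entries")
    evals, evecs = np.linalg.eigh(0.5 * (K + K.T))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_clip = int((evals < 0).sum())
    if n_clip:
        logger.info("eigendecompose: clipped %d negative eigenvalues to 0", n_clip)
    return Spectrum(np.maximum(evals, 0.0), evecs, n_markers)


@dataclass
class _Rotated:
    """Spectrum-rotated data reused across likelihood evaluations."""

    lam_m: np.ndarray  # lambda_i / m
    y: np.ndarray  # U^T y_s1
    X: np.ndarray  # U^T X
    s1: int
    k: int


def _rotate(spectrum: Spectrum, ys1: np.ndarray, X: np.ndarray) -> _Rotated:
    U = spectrum.eigenvectors
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return _Rotated(
        lam_m=spectrum.eigenvalues / spectrum.n_markers,
        y=U.T @ np.asarray(ys1, dtype=float),
        X=U.T @ X,
        s1=len(ys1),
        k=X.shape[1],
    )


def profile_loglik(
    tau: float,
    spectrum: Spectrum,
    ys1: np.ndarray,
    X: np.ndarray,
    mode: str = "ML",
):
    """Profile log-likelihood and its theta = log(tau) derivatives.

    Returns (value, d/dtheta, d2/dtheta2, beta_hat, sigma_g2_hat).
    """
    rot = _rotate(spectrum, ys1, X)
    return _profile_loglik(tau, rot, mode)


def _profile_loglik(tau: float, rot: _Rotated, mode: str):
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if mode not in ("ML", "REML"):
        raise ValueError(f"mode must be ML or REML, got {mode!r}")
    D = rot.lam_m + tau
    assert np.all(D > 0), "H_tau not positive definite"
    d1, d2, d3 = 1.0 / D, 1.0 / D**2, 1.0 / D**3
    yt, Xt, s1, k = rot.y, rot.X, rot.s1, rot.k
    dof = s1 if mode == "ML" else s1 - k

    if k:
        A = Xt.T @ (Xt * d1[:, None])
        b = Xt.T @ (yt * d1)
        beta = np.linalg.solve(A, b)
        r = yt - Xt @ beta
    else:
        A = np.empty((0, 0))
        beta = np.empty(0)
        r = yt

    Q = float(r @ (r * d1))
    if Q <= 0:
        raise FloatingPointError("non-positive residual quadratic form")
    sigma_g2 = Q / dof

    # dQ/dtau by the envelope theorem; d2Q/dtau2 tracks the moving beta^
    Qp = -float(r @ (r * d2))
    if k:
        c = Xt.T @ (r * d2)
        Ainv_c = np.linalg.solve(A, c)
        Qpp = 2.0 * float(r @ (r * d3)) - 2.0 * float(c @ Ainv_c)
    else:
        Qpp = 2.0 * float(r @ (r * d3))

    logdetD = float(np.log(D).sum())
    value = -0.5 * (dof * np.log(2.0 * np.pi * sigma_g2) + logdetD + dof)
    # d/dtau of [dof*log Q + sum log D]  (the parts that vary with tau)
    dl_dtau = -0.5 * (dof * Qp / Q + float(d1.sum()))
    d2l_dtau2 = -0.5 * (dof * (Qpp * Q - Qp**2) / Q**2 - float(d2.sum()))

    if mode == "REML" and k:
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise FloatingPointError("X^T H^-1 X not positive definite")
        value += -0.5 * logdetA
        M = Xt.T @ (Xt * d2[:, None])
        N = Xt.T @ (Xt * d3[:, None])
        AinvM = np.linalg.solve(A, M)
        AinvN = np.linalg.solve(A, N)
        # d/dtau log det A = -tr(A^-1 M); second derivative as below
        dl_dtau += 0.5 * float(np.trace(AinvM))
        d2l_dtau2 += -0.5 * (-float(np.trace(AinvM @ AinvM)) + 2.0 * float(np.trace(AinvN)))

    # chain rule to theta = log tau
    dl_dtheta = tau * dl_dtau
    d2l_dtheta2 = tau**2 * d2l_dtau2 + dl_dtheta
    return value, dl_dtheta, d2l_dtheta2, beta, sigma_g2


def _golden_section(f, lo: float, hi: float, tol: float = 1e-10, max_iter: int = 200):
    """Maximize a unimodal f on [lo, hi] by golden-section search."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
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


def fit_variance_components(
    spectrum: Spectrum,
    ys1: np.ndarray,
    X: np.ndarray,
    init_tau: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    mode: str = "ML",
) -> VarianceComponents:
    """Newton's method on theta = log(tau), with ascent-guarded steps.

    Steps that do not increase the profile log-likelihood are halved; if
    Newton fails to converge in ``max_iter`` iterations, a golden-section
    search over theta in [log 1e-6, log 1e6] takes over and the fit is
    flagged as not Newton-converged.
    """
    if init_tau <= 0:
        raise ValueError(f"init_tau must be positive, got {init_tau}")
    rot = _rotate(spectrum, ys1, X)

    def ll(theta: float) -> float:
        return _profile_loglik(float(np.exp(theta)), rot, mode)[0]

    theta = float(np.log(init_tau))
    trace = [theta]
    value, grad, hess, beta, sg2 = _profile_loglik(np.exp(theta), rot, mode)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite log-likelihood; tau trace: {np.exp(trace)}")
        if abs(grad) < tol:
            converged = True
            break
        step = -grad / hess if hess < 0 else float(np.sign(grad))
        step = float(np.clip(step, -5.0, 5.0))
        # halve until the likelihood does not decrease
        new_theta, new_value = theta, value
        for _ in range(40):
            cand = float(np.clip(theta + step, THETA_LO, THETA_HI))
            cand_value = ll(cand)
            if cand_value >= value - 1e-13:
                new_theta, new_value = cand, cand_value
                break
            step *= 0.5
        if abs(new_theta - theta) < tol:
            theta, value = new_theta, new_value
            converged = True
            break
        theta, value = new_theta, new_value
        trace.append(theta)
        value, grad, hess, beta, sg2 = _profile_loglik(np.exp(theta), rot, mode)

    newton_ok = converged
    if not converged:
        logger.info("Newton did not converge in %d iterations; golden-section fallback", max_iter)
        theta, value = _golden_section(ll, THETA_LO, THETA_HI)

    # global safeguard: the profile can be multimodal on small or degenerate
    # instances (e.g. a full-rank K that fits the response at tau -> 0); a
    # coarse grid detects a better basin, which golden section then refines
    grid = np.linspace(THETA_LO, THETA_HI, 129)
    grid_vals = np.array([ll(t) for t in grid])
    i_best = int(np.argmax(grid_vals))
    if grid_vals[i_best] > ll(theta) + 1e-10:
        lo = grid[max(i_best - 1, 0)]
        hi = grid[min(i_best + 1, len(grid) - 1)]
        theta, _ = _golden_section(ll, lo, hi)
        newton_ok = False
        logger.info("profile maximum found away from Newton basin; tau=%.3g", np.exp(theta))

    # polish: a few guarded Newton steps drive the gradient to roundoff
    for _ in range(5):
        value, grad, hess, beta, sg2 = _profile_loglik(np.exp(theta), rot, mode)
        if abs(grad) < 1e-12 or hess >= 0:
            break
        cand = float(np.clip(theta - grad / hess, THETA_LO, THETA_HI))
        if ll(cand) < value or cand == theta:
            break
        theta = cand
    value, grad, hess, beta, sg2 = _profile_loglik(np.exp(theta), rot, mode)

    tau = float(np.exp(theta))
    vc = VarianceComponents(
        tau=tau,
        sigma_g2=float(sg2),
        beta=beta,
        loglik=float(value),
        iterations=it,
        converged=True,
        mode=mode,
        newton_converged=newton_ok,
    )
    logger.info(
        "varcomp (%s): tau=%.6g sigma_g2=%.6g sigma_e2=%.6g h2=%.4f loglik=%.6f iters=%d",
        mode, vc.tau, vc.sigma_g2, vc.sigma_e2, vc.h2, vc.loglik, it,
    )
    return vc


def fit_report(vc: VarianceComponents) -> str:
    """Human-readable fit summary."""
    lines = [
        f"mode          {vc.mode}",
        f"tau           {vc.tau:.6g}",
        f"sigma_g2      {vc.sigma_g2:.6g}",
        f"sigma_e2      {vc.sigma_e2:.6g}",
        f"h2            {vc.h2:.6f}",
        f"loglik        {vc.loglik:.6f}",
        f"iterations    {vc.iterations}",
        f"newton_converged  {vc.newton_converged}",
    ]
    return "\n".join(lines) + "\n"
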