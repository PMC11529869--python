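"""Population-structure covariates in sketched-sample space.

The top principal components of the sample-sketched genotype matrix Z_s1
stand in for the usual genotype PCs: left-sketching preserves the dominant
subspace, so ancestry axes survive the projection.  The covariate matrix
(intercept, PCs, user covariates) is assembled entirely in sketched space —
original-sample covariates are pushed through the same S1 so that every
column lives where the model is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .sketch import SketchOperator

logger = logging.getLogger("masklmm")


@dataclass
class CovariateMatrix:
    X: np.ndarray  # s1 x k
    labels: list[str]

    @property
    def k(self) -> int:
        return self.X.shape[1]


def top_pcs(Zs1: np.ndarray, q: int, seed: int | None = None) -> np.ndarray:
    """Top-q PC scores (left singular vectors scaled by singular values).

    Columns of Z_s1 are centered first (marker columns were normalized
    against the original samples, so sketched rows carry a stray mean).
    Scores are computed from the eigendecomposition of the small s1 x s1
    Gram matrix, which is exact for the leading components; sign is fixed
    by making the largest-magnitude loading of each score positive.
    ``seed`` is accepted for interface stability; the decomposition is
    deterministic.
    """
    Zs1 = np.asarray(Zs1, dtype=float)
    s1, m = Zs1.shape
    if not 1 <= q < min(s1, m):
        raise ValueError(f"q must satisfy 1 <= q < min(s1, m) = {min(s1, m)}, got {q}")
    A = Zs1 - Zs1.mean(axis=0, keepdims=True)
    G = A @ A.T
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:q]
    lam = evals[order]
    if lam[-1] <= max(lam[0], 1.0) * 1e-12:
        raise ValueError(
            f"PC {q} has (near-)zero variance; the sketched matrix has rank < {q}"
        )
    scores = evecs[:, order] * np.sqrt(lam)
    # deterministic sign: largest-|.| entry of each score positive
    flips = np.sign(scores[np.abs(scores).argmax(axis=0), np.arange(q)])
    return scores * flips


def build_covariates(
    pcs: np.ndarray | None,
    user_covars: np.ndarray | None,
    S1: SketchOperator,
    include_intercept: bool = True,
    user_labels: list[str] | None = None,
) -> CovariateMatrix:
    """Assemble X = [S1·1 | PCs | S1·user_covars] in sketched-sample space.

    The intercept of the unsketched model maps to the column S1·1 under
    left-sketching, so that column (not a constant) plays the intercept
    role here.  The result must be full column rank; the first column that
    is linearly dependent on its predecessors is named in the error.
    """
    cols: list[np.ndarray] = []
    labels: list[str] = []
    if include_intercept:
        cols.append(S1.apply_left(np.ones(S1.in_dim)))
        labels.append("intercept")
    if pcs is not None and pcs.size:
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        for j in range(pcs.shape[1]):
            cols.append(pcs[:, j])
            labels.append(f"PC{j + 1}")
    if user_covars is not None and np.size(user_covars):
        C = np.asarray(user_covars, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Cs = S1.apply_left(C)
        names = user_labels or [f"COV{j + 1}" for j in range(C.shape[1])]
        for j in range(Cs.shape[1]):
            cols.append(Cs[:, j])
            labels.append(names[j])
    if not cols:
        return CovariateMatrix(X=np.empty((S1.out_dim, 0)), labels=[])
    X = np.column_stack(cols)
    if X.shape[1] >= X.shape[0]:
        raise ValueError(f"{X.shape[1]} covariates for only {X.shape[0]} sketched samples")
    _check_rank(X, labels)
    return CovariateMatrix(X=X, labels=labels)


def _check_rank(X: np.ndarray, labels: list[str], rtol: float = 1e-10) -> None:
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] > rtol * sv[0]:
        return
    # locate the first offending column by incremental QR
    Q = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        r = v - Q @ (Q.T @ v)
        if np.linalg.norm(r) <= rtol * max(norm0, 1.0):
            raise ValueError(f"covariate column {labels[j]!r} is collinear with earlier columns")
        Q = np.column_stack([Q, r / np.linalg.norm(r)])
    raise ValueError("covariate matrix is rank deficient")
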