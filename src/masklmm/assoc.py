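"""Per-marker association scan in sketched-sample space.

For each retained marker column z of Z_s1 the score-type statistic

    chi^2 = (z~' V^-1 y~)^2 / (z~' V^-1 z~),    V = sigma_g^2 H_tau,

is referred to a chi-squared distribution with one degree of freedom.
Covariates are handled by generalized-least-squares residualization: both
the sketched response and the tested column are projected off X under the
V^-1 inner product first, which reduces to the plain formula when X is
empty.  V^-1 is applied through the stored eigendecomposition of K, so the
scan is a handful of dense matrix products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plinkio import VariantRecord
from .varcomp import Spectrum, VarianceComponents

logger = logging.getLogger("masklmm")

#: denominators below this are reported as untestable (chi2 = 0, p = 1)
DEGENERATE_DEN = 1e-12


class VInverse:
    """The linear operator V^-1 = U diag(1/(sigma_g^2 (lambda_i/m + tau))) U^T."""

    def __init__(self, vc: VarianceComponents, spectrum: Spectrum):
        if vc.sigma_g2 <= 0:
            raise ValueError(
                "sigma_g2 is zero: V is singular; refit with the null model V = sigma_e2 * I"
            )
        self.U = spectrum.eigenvectors
        self.weights = 1.0 / (
            vc.sigma_g2 * (spectrum.eigenvalues / spectrum.n_markers + vc.tau)
        )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return self.U @ (self.weights * (self.U.T @ x))
        return self.U @ (self.weights[:, None] * (self.U.T @ x))


def v_inverse_apply(vc: VarianceComponents, spectrum: Spectrum) -> VInverse:
    """Build the V^-1 operator from a fitted model and the GRM spectrum."""
    return VInverse(vc, spectrum)


@dataclass
class AssociationResult:
    table: pd.DataFrame  # CHR SNP BP A1 A2 CHISQ P (+DEGENERATE flag)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


def scan(
    Zs1: np.ndarray,
    ys1: np.ndarray,
    X: np.ndarray,
    vinv: VInverse,
    variants: list[VariantRecord],
    metadata: dict | None = None,
) -> AssociationResult:
    """chi^2 and p-value for every retained marker, rows in BIM order."""
    Zs1 = np.asarray(Zs1, dtype=float)
    ys1 = np.asarray(ys1, dtype=float)
    s1, m = Zs1.shape
    if len(ys1) != s1 or len(variants) != m:
        raise ValueError(
            f"inconsistent shapes: Zs1 {Zs1.shape}, ys1 {ys1.shape}, {len(variants)} variants"
        )
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    k = X.shape[1]

    if k:
        if X.shape[0] != s1:
            raise ValueError(f"covariates have {X.shape[0]} rows, expected {s1}")
        VX = vinv(X)
        A = X.T @ VX
        y_res = ys1 - X @ np.linalg.solve(A, VX.T @ ys1)
        Z_res = Zs1 - X @ np.linalg.solve(A, VX.T @ Zs1)
    else:
        y_res = ys1
        Z_res = Zs1

    Vy = vinv(y_res)
    VZ = vinv(Z_res)
    num = Z_res.T @ Vy
    den = np.einsum("ij,ij->j", Z_res, VZ)
    degenerate = den < DEGENERATE_DEN
    if degenerate.any():
        logger.info("scan: %d markers untestable (degenerate denominator)", degenerate.sum())
    chisq = np.zeros(m)
    np.divide(num**2, den, out=chisq, where=~degenerate)
    chisq = np.maximum(chisq, 0.0)
    p = np.where(degenerate, 1.0, sps.chi2.sf(chisq, df=1))

    table = pd.DataFrame(
        {
            "CHR": [v.chrom for v in variants],
            "SNP": [v.id for v in variants],
            "BP": [v.bp for v in variants],
            "A1": [v.a1 for v in variants],
            "A2": [v.a2 for v in variants],
            "CHISQ": chisq,
            "P": p,
            "DEGENERATE": degenerate,
        }
    )
    return AssociationResult(table=table, metadata=metadata or {})


def write_summary(results: AssociationResult, path: str | Path) -> None:
    """Write the CHR SNP BP A1 A2 CHISQ P table as TSV (P in scientific form)."""
    if len(results) == 0:
        raise ValueError("no association results to write")
    df = results.table
    try:
        with open(path, "w") as fh:
            fh.write("CHR\tSNP\tBP\tA1\tA2\tCHISQ\tP\n")
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.CHR}\t{row.SNP}\t{row.BP}\t{row.A1}\t{row.A2}\t"
                    f"{row.CHISQ:.8g}\t{row.P:.6e}\n"
                )
    except OSError as exc:
        raise OSError(f"cannot write summary to {path}: {exc}") from exc
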