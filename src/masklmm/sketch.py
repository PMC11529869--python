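"""Seeded Gaussian sketching of genotypes, response and GRM.

A sample sketch S1 (s1 x n) compresses individuals; a marker sketch S2
(m x s2) compresses markers inside the GRM only.  Entries are i.i.d.
N(0, 1/s) with s the sketch dimension, so inner products and norms are
preserved in expectation (Johnson-Lindenstrauss).  The sketched quantities

    Z_s1 = S1 Z,   y_s1 = S1 y,   K = S1 Z S2 S2^T Z^T S1^T

replace Z, y and Z Z^T downstream.

Entries are generated counter-based: the stream for input index j is keyed
by (seed, j), so any block partition of the data materializes exactly the
same operator — streaming order cannot change results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .plinkio import GenotypeSource, NormalizationPolicy, VariantRecord, stream_blocks

logger = logging.getLogger("masklmm")

DEFAULT_BLOCK_SIZE = 1024


@dataclass(frozen=True)
class SketchOperator:
    """A seeded random projection, materializable per index range.

    ``orientation`` "left" means the operator is (out_dim x in_dim) and is
    applied from the left (columns indexed by the data dimension);
    "right" means (in_dim x out_dim), applied from the right (rows indexed
    by the data dimension).  ``kind`` "identity" gives the exact identity
    (out_dim == in_dim), used to recover the unsketched computation.
    """

    kind: str  # {"gaussian", "identity"}
    out_dim: int
    in_dim: int
    seed: int = 0
    orientation: str = "left"  # {"left", "right"}

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "identity"):
            raise ValueError(f"unknown sketch kind {self.kind!r}")
        if self.orientation not in ("left", "right"):
            raise ValueError(f"orientation must be left or right, got {self.orientation!r}")
        if not 1 <= self.out_dim <= self.in_dim:
            raise ValueError(
                f"sketch dimension exceeds data dimension: out_dim={self.out_dim}, "
                f"in_dim={self.in_dim}"
            )
        if self.kind == "identity" and self.out_dim != self.in_dim:
            raise ValueError("identity sketch requires out_dim == in_dim")

    @property
    def is_identity(self) -> bool:
        return self.kind == "identity"

    def _stream(self, index: int) -> np.ndarray:
        """The out_dim N(0, 1/out_dim) variates attached to input index ``index``."""
        bg = np.random.Philox(key=np.array([np.uint64(self.seed), np.uint64(index)]))
        return np.random.Generator(bg).standard_normal(self.out_dim) / np.sqrt(self.out_dim)

    def materialize(self, lo: int = 0, hi: int | None = None) -> np.ndarray:
        """Columns [lo, hi) for a left operator; rows [lo, hi) for a right one.

        Deterministic in (seed, index range) and independent of the order
        ranges are requested.
        """
        if hi is None:
            hi = self.in_dim
        if not 0 <= lo <= hi <= self.in_dim:
            raise IndexError(f"range [{lo}, {hi}) outside [0, {self.in_dim})")
        if self.is_identity:
            eye = np.zeros((self.out_dim, hi - lo))
            eye[lo:hi, :] = np.eye(hi - lo)
            return eye if self.orientation == "left" else eye.T
        block = np.empty((hi - lo, self.out_dim))
        for i, j in enumerate(range(lo, hi)):
            block[i] = self._stream(j)
        return block.T if self.orientation == "left" else block

    def apply_left(self, data: np.ndarray) -> np.ndarray:
        """S @ data for a left operator, with the identity short-circuited."""
        if self.orientation != "left":
            raise ValueError("apply_left requires a left-oriented operator")
        if data.shape[0] != self.in_dim:
            raise ValueError(f"data has {data.shape[0]} rows, operator expects {self.in_dim}")
        if self.is_identity:
            return np.asarray(data, dtype=float)
        return self.materialize() @ data


def make_sketch(
    out_dim: int,
    in_dim: int,
    seed: int = 0,
    orientation: str = "left",
    kind: str = "gaussian",
) -> SketchOperator:
    """Construct a seeded Gaussian (or identity test-mode) sketch operator."""
    return SketchOperator(kind=kind, out_dim=out_dim, in_dim=in_dim, seed=seed, orientation=orientation)


@dataclass
class SketchedData:
    """Everything the downstream model needs in sketched-sample space."""

    Zs1: np.ndarray
    ys1: np.ndarray
    K: np.ndarray
    s1: int
    s2: int
    variants: list[VariantRecord] = field(default_factory=list)
    marker_indices: np.ndarray | None = None
    seeds: dict = field(default_factory=dict)


def sketch_samples(
    source: GenotypeSource,
    policy: NormalizationPolicy,
    S1: SketchOperator,
    block_size: int = DEFAULT_BLOCK_SIZE,
    sample_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, list[VariantRecord]]:
    """Compute Z_s1 = S1 Z block-by-block over the retained markers."""
    n_used = source.n if sample_indices is None else len(sample_indices)
    if S1.in_dim != n_used:
        raise ValueError(f"S1 expects {S1.in_dim} samples but {n_used} are usable")
    kept = source.retained_markers(policy, sample_indices)
    if kept.size == 0:
        logger.warning("no markers retained after filtering; sketch is empty")
        return np.empty((S1.out_dim, 0)), []
    S = None if S1.is_identity else S1.materialize()
    Zs1 = np.empty((S1.out_dim, kept.size))
    for block in stream_blocks(source, policy, block_size, sample_indices):
        lo, hi = block.marker_range
        Zs1[:, lo:hi] = block.data if S is None else S @ block.data
    variants = [source.variants[i] for i in kept]
    return Zs1, variants


def sketch_response(y: np.ndarray, S1: SketchOperator) -> np.ndarray:
    """y_s1 = S1 y."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != S1.in_dim:
        raise ValueError(f"response has length {y.shape[0]}, operator expects {S1.in_dim}")
    return S1.apply_left(y)


def sketched_grm(
    source: GenotypeSource,
    policy: NormalizationPolicy,
    S1: SketchOperator,
    S2: SketchOperator,
    block_size: int = DEFAULT_BLOCK_SIZE,
    sample_indices: np.ndarray | None = None,
) -> np.ndarray:
    """K = S1 Z S2 S2^T Z^T S1^T, accumulated in marker blocks.

    The intermediate B = S1 Z S2 (s1 x s2) is the doubly sketched genotype
    matrix; K = B B^T is symmetric positive semidefinite by construction.
    """
    kept = source.retained_markers(policy, sample_indices)
    if S2.in_dim != kept.size:
        raise ValueError(f"S2 expects {S2.in_dim} markers but {kept.size} are retained")
    S = None if S1.is_identity else S1.materialize()
    B = np.zeros((S1.out_dim, S2.out_dim))
    for block in stream_blocks(source, policy, block_size, sample_indices):
        lo, hi = block.marker_range
        left = block.data if S is None else S @ block.data
        B += left @ S2.materialize(lo, hi)
    K = B @ B.T
    return 0.5 * (K + K.T)


def grm_from_sketched(
    Zs1: np.ndarray, S2: SketchOperator, block_size: int = DEFAULT_BLOCK_SIZE
) -> np.ndarray:
    """K from an already sample-sketched Z_s1 (avoids a second streaming pass)."""
    m = Zs1.shape[1]
    if S2.in_dim != m:
        raise ValueError(f"S2 expects {S2.in_dim} markers but Zs1 has {m}")
    B = np.zeros((Zs1.shape[0], S2.out_dim))
    for lo in range(0, m, block_size):
        hi = min(lo + block_size, m)
        B += Zs1[:, lo:hi] @ S2.materialize(lo, hi)
    K = B @ B.T
    return 0.5 * (K + K.T)


class OrthonormalizedSketch:
    """A Gaussian sample sketch with its rows orthonormalized.

    For Gaussian noise e ~ N(0, I) the raw sketched residual S1 e has
    covariance S1 S1^T — a Wishart matrix, not the identity the model's
    tau*I term assumes, which mis-calibrates the scan at small s1/n.
    Replacing S1 by L^-1 S1, where L is the Cholesky factor of S1 S1^T,
    yields an operator with exactly orthonormal rows: the sketched noise is
    white and the mixed-model form holds exactly.  The span (and hence the
    information kept) is unchanged.
    """

    def __init__(self, base: SketchOperator):
        if base.orientation != "left":
            raise ValueError("orthonormalization applies to left (sample) sketches")
        self.base = base
        S = base.materialize()
        self._S = _tri_solve(np.linalg.cholesky(S @ S.T), S)

    kind = "gaussian-orthonormal"

    @property
    def out_dim(self) -> int:
        return self.base.out_dim

    @property
    def in_dim(self) -> int:
        return self.base.in_dim

    @property
    def seed(self) -> int:
        return self.base.seed

    orientation = "left"
    is_identity = False

    def materialize(self, lo: int = 0, hi: int | None = None) -> np.ndarray:
        if hi is None:
            hi = self.in_dim
        return self._S[:, lo:hi]

    def apply_left(self, data: np.ndarray) -> np.ndarray:
        if data.shape[0] != self.in_dim:
            raise ValueError(f"data has {data.shape[0]} rows, operator expects {self.in_dim}")
        return self._S @ data


def _tri_solve(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    return solve_triangular(L, B, lower=True)


def resolve_sketch_dim(spec: float | int, full_dim: int) -> int:
    """Turn a fraction in (0, 1] or an absolute count into a sketch dimension."""
    if isinstance(spec, float) and 0 < spec <= 1.0:
        return min(full_dim, int(np.ceil(spec * full_dim)))
    s = int(spec)
    if not 1 <= s <= full_dim:
        raise ValueError(f"sketch dimension {s} outside [1, {full_dim}]")
    return s


def resolve_sketch(
    spec: float | int,
    full_dim: int,
    seed: int,
    orientation: str,
    orthonormalize: bool = False,
) -> SketchOperator | OrthonormalizedSketch:
    """Build the operator the pipeline uses for a requested sketch size.

    A resolved dimension equal to the full dimension yields the identity:
    projecting onto as many Gaussian directions as the space has dimensions
    reduces nothing and only injects noise, so the natural limit of the
    sketch at fraction 1.0 is no sketching at all.  With ``orthonormalize``
    (the pipeline default for the sample sketch) a Gaussian operator is
    row-orthonormalized so the sketched residual stays white.
    """
    s = resolve_sketch_dim(spec, full_dim)
    if s == full_dim:
        return make_sketch(s, full_dim, seed=seed, orientation=orientation, kind="identity")
    op = make_sketch(s, full_dim, seed=seed, orientation=orientation)
    if orthonormalize and orientation == "left":
        return OrthonormalizedSketch(op)
    return op
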