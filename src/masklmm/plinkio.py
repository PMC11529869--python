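"""PLINK 1 binary genotype I/O and streaming normalization.

Reads and writes BED/BIM/FAM triplets (SNP-major, PLINK 1.9 two-bit
encoding), plus whitespace-delimited phenotype and covariate tables keyed by
(FID, IID).  Genotypes are decoded lazily in marker blocks so the full
``n x m`` matrix never has to reside in memory; each block is returned
already normalized to the standard GRM convention

    w = (g - 2 p) / sqrt(2 p (1 - p)),

with missing hard calls imputed to the per-marker mean dosage ``2 p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("masklmm")

BED_MAGIC = b"\x6c\x1b"
SNP_MAJOR = b"\x01"

#: missing-dosage sentinel used in integer dosage matrices
MISSING = -1

#: phenotype missing codes (PLINK convention plus NA strings)
PHENO_MISSING_CODES = {"-9", "-9.0", "NA", "NaN", "nan", "na"}

# PLINK 1.9 two-bit code -> dosage of allele a1:
#   0b00 = 2 copies of a1, 0b01 = missing, 0b10 = het, 0b11 = 0 copies.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Malformed BED/BIM/FAM content."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    id: str
    cm: float
    bp: int
    a1: str
    a2: str


@dataclass(frozen=True)
class SampleRecord:
    fid: str
    iid: str
    sex: int = 0
    pheno_slot: float = -9.0


@dataclass(frozen=True)
class NormalizationPolicy:
    """Marker filtering and scaling rules applied before sketching.

    maf_min: markers with minor-allele frequency below this are dropped.
    Missing hard calls are imputed to the marker mean 2p; retained columns
    are centered by 2p and scaled by sqrt(2p(1-p)).  Zero-variance markers
    are always dropped (the association statistic is undefined for them).
    """

    maf_min: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError(f"maf_min must lie in [0, 0.5), got {self.maf_min}")


@dataclass(frozen=True)
class AlleleStats:
    """Per-marker a1 allele frequency, missing fraction and dosage variance."""

    freq: np.ndarray
    missing_frac: np.ndarray
    dosage_var: np.ndarray


@dataclass
class GenotypeBlock:
    """A normalized slice of the genotype matrix.

    ``data`` is samples x markers; ``marker_range`` is a half-open interval
    into the *retained* marker list and ``marker_indices`` gives the
    original BIM row of each column.
    """

    data: np.ndarray
    marker_range: tuple[int, int]
    marker_indices: np.ndarray


class GenotypeSource:
    """Handle over a BED/BIM/FAM triplet; payload stays on disk (memmap)."""

    def __init__(self, prefix: str | Path):
        prefix = Path(prefix)
        for ext in (".bed", ".bim", ".fam"):
            if not prefix.with_suffix(ext).exists():
                raise FileNotFoundError(f"missing PLINK file: {prefix.with_suffix(ext)}")
        self.prefix = prefix
        self.variants = _read_bim(prefix.with_suffix(".bim"))
        self.samples = _read_fam(prefix.with_suffix(".fam"))
        self.n = len(self.samples)
        self.m = len(self.variants)
        keys = [(s.fid, s.iid) for s in self.samples]
        if len(set(keys)) != self.n:
            raise PlinkFormatError(f"duplicate (FID, IID) pairs in {prefix.with_suffix('.fam')}")

        bed_path = prefix.with_suffix(".bed")
        with open(bed_path, "rb") as fh:
            header = fh.read(3)
        if len(header) < 3 or header[:2] != BED_MAGIC:
            raise PlinkFormatError(f"{bed_path}: bad magic bytes {header[:2]!r}")
        if header[2:3] != SNP_MAJOR:
            raise PlinkFormatError(f"{bed_path}: not SNP-major (mode byte {header[2]:#04x})")
        self._bytes_per_snp = (self.n + 3) // 4
        expected = 3 + self._bytes_per_snp * self.m
        actual = bed_path.stat().st_size
        if actual != expected:
            raise PlinkFormatError(
                f"{bed_path}: payload is {actual - 3} bytes, expected "
                f"{expected - 3} (= ceil({self.n}/4) * {self.m})"
            )
        self._payload = np.memmap(bed_path, dtype=np.uint8, mode="r", offset=3).reshape(
            self.m, self._bytes_per_snp
        )
        self._stats_cache: dict[tuple | None, AlleleStats] = {}

    # -- raw dosage access ------------------------------------------------

    def dosages(self, marker_lo: int = 0, marker_hi: int | None = None) -> np.ndarray:
        """Decode raw dosages (n x b int8, missing = -1) for markers [lo, hi)."""
        if marker_hi is None:
            marker_hi = self.m
        raw = np.asarray(self._payload[marker_lo:marker_hi])  # b x bytes
        # unpack 2-bit fields, little-endian within each byte
        codes = (raw[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 0b11
        codes = codes.reshape(raw.shape[0], -1)[:, : self.n]
        return _CODE_TO_DOSAGE[codes].T.copy()  # n x b

    def allele_stats(self, sample_indices: np.ndarray | None = None) -> AlleleStats:
        """Per-marker a1 frequency / missingness / variance on the given samples."""
        key = None if sample_indices is None else tuple(np.asarray(sample_indices).tolist())
        if key in self._stats_cache:
            return self._stats_cache[key]
        n_used = self.n if sample_indices is None else len(sample_indices)
        freq = np.empty(self.m)
        miss = np.empty(self.m)
        var = np.empty(self.m)
        step = max(1, (1 << 22) // max(self._bytes_per_snp, 1))
        for lo in range(0, self.m, step):
            hi = min(lo + step, self.m)
            g = self.dosages(lo, hi)
            if sample_indices is not None:
                g = g[sample_indices]
            observed = g != MISSING
            n_obs = observed.sum(axis=0)
            gf = np.where(observed, g, 0).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = gf.sum(axis=0) / n_obs
                ex2 = (gf**2).sum(axis=0) / n_obs
            freq[lo:hi] = np.where(n_obs > 0, mean / 2.0, np.nan)
            miss[lo:hi] = 1.0 - n_obs / n_used
            var[lo:hi] = np.where(n_obs > 0, ex2 - mean**2, 0.0)
        stats = AlleleStats(freq=freq, missing_frac=miss, dosage_var=var)
        self._stats_cache[key] = stats
        return stats

    def retained_markers(
        self,
        policy: NormalizationPolicy,
        sample_indices: np.ndarray | None = None,
    ) -> np.ndarray:
        """Original indices of markers surviving the MAF / variance filter."""
        stats = self.allele_stats(sample_indices)
        with np.errstate(invalid="ignore"):
            maf = np.minimum(stats.freq, 1.0 - stats.freq)
            keep = (
                np.isfinite(stats.freq)
                & (maf >= policy.maf_min)
                & (stats.dosage_var > 1e-12)
                & (stats.missing_frac < 1.0)
            )
        kept = np.flatnonzero(keep)
        logger.info(
            "marker filter: %d of %d retained (maf_min=%g)", kept.size, self.m, policy.maf_min
        )
        return kept


def open_bed(prefix: str | Path) -> GenotypeSource:
    """Open a PLINK binary fileset; metadata parsed, payload memory-mapped."""
    return GenotypeSource(prefix)


def _read_bim(path: Path) -> list[VariantRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise PlinkFormatError(f"{path}:{ln}: expected 6 BIM columns, got {len(parts)}")
            chrom, vid, cm, bp, a1, a2 = parts
            if not vid:
                raise PlinkFormatError(f"{path}:{ln}: empty variant id")
            bp_i = int(bp)
            if bp_i < 0:
                raise PlinkFormatError(f"{path}:{ln}: negative position {bp_i}")
            records.append(VariantRecord(chrom, vid, float(cm), bp_i, a1, a2))
    return records


def _read_fam(path: Path) -> list[SampleRecord]:
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise PlinkFormatError(f"{path}:{ln}: expected 6 FAM columns, got {len(parts)}")
            fid, iid, _pat, _mat, sex, pheno = parts[:6]
            records.append(SampleRecord(fid, iid, int(float(sex)), float(pheno)))
    return records


def stream_blocks(
    source: GenotypeSource,
    policy: NormalizationPolicy,
    block_size: int,
    sample_indices: np.ndarray | None = None,
) -> Iterator[GenotypeBlock]:
    """Yield normalized genotype blocks covering every retained marker once.

    Blocks are contiguous, non-overlapping slices of the retained marker
    list, in BIM order.  Normalization uses allele frequencies computed on
    ``sample_indices`` (all samples if None), so every retained column of a
    yielded block has mean ~0 on exactly those samples.
    """
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    stats = source.allele_stats(sample_indices)
    kept = source.retained_markers(policy, sample_indices)
    for lo in range(0, kept.size, block_size):
        hi = min(lo + block_size, kept.size)
        idx = kept[lo:hi]
        # retained markers are nearly contiguous; decode the covering range
        g = source.dosages(idx[0], idx[-1] + 1)[:, idx - idx[0]].astype(float)
        if sample_indices is not None:
            g = g[sample_indices]
        p = stats.freq[idx]
        g[g == MISSING] = np.nan
        g = np.where(np.isnan(g), 2.0 * p, g)
        w = (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
        yield GenotypeBlock(data=w, marker_range=(lo, hi), marker_indices=idx)


def write_bed(
    dosages: np.ndarray,
    variants: Sequence[VariantRecord],
    samples: Sequence[SampleRecord],
    prefix: str | Path,
) -> None:
    """Write an n x m integer dosage matrix (entries {0,1,2,-1}) as BED/BIM/FAM."""
    dosages = np.asarray(dosages)
    n, m = dosages.shape if dosages.ndim == 2 else (len(dosages), 1)
    if len(variants) == 0:
        raise ValueError("empty variant list")
    if n != len(samples) or m != len(variants):
        raise ValueError(
            f"dosage matrix is {n}x{m} but {len(samples)} samples / {len(variants)} variants given"
        )
    bad = ~np.isin(dosages, (0, 1, 2, MISSING))
    if bad.any():
        raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    code = np.empty_like(dosages, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        code[dosages == d] = c
    n_pad = (-n) % 4
    if n_pad:
        code = np.vstack([code, np.zeros((n_pad, m), dtype=np.uint8)])
    code = code.T.reshape(m, -1, 4)  # m x bytes x 4 two-bit fields
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    payload = (code << shifts).sum(axis=2, dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC + SNP_MAJOR)
        fh.write(payload.tobytes())
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.id}\t{v.cm:g}\t{v.bp}\t{v.a1}\t{v.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in samples:
            fh.write(f"{s.fid}\t{s.iid}\t0\t0\t{s.sex}\t{s.pheno_slot:g}\n")


# -- phenotype / covariate tables ----------------------------------------


@dataclass
class Phenotype:
    """Phenotype aligned to a genotype source.

    ``values`` holds the normalized (zero-mean, unit-variance) phenotype of
    the usable samples; ``sample_indices`` maps each entry back to a row of
    the genotype source.  Samples missing from the file or carrying a
    missing code are excluded.
    """

    values: np.ndarray
    sample_indices: np.ndarray
    n_missing: int = 0


def _read_keyed_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as fh:
        first = fh.readline().split()
    if not first or len(first) < 2:
        raise ValueError(f"{path}: expected at least FID and IID columns")
    has_header = first[0].upper() in {"FID", "#FID"}
    df = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None, dtype=str)
    if not has_header:
        df.columns = ["FID", "IID"] + [f"V{i}" for i in range(1, df.shape[1] - 1)]
    else:
        df = df.rename(columns={df.columns[0]: "FID", df.columns[1]: "IID"})
    return df


def _align(df: pd.DataFrame, source: GenotypeSource, path: str | Path) -> pd.DataFrame:
    df = df.set_index(df["FID"].astype(str) + "\t" + df["IID"].astype(str))
    keys = [f"{s.fid}\t{s.iid}" for s in source.samples]
    present = [k for k in keys if k in df.index]
    if not present:
        raise ValueError(f"{path}: no samples overlap the genotype FAM")
    return df.reindex(keys)


def read_phenotype(
    path: str | Path, source: GenotypeSource, column: str | None = None
) -> Phenotype:
    """Read one phenotype column, align to FAM order, center and scale it.

    Samples absent from the file or holding a missing code (-9 / NA) are
    dropped; the survivors are mean-centered and scaled to unit variance
    (the normalized response the model expects).
    """
    df = _read_keyed_table(path)
    value_cols = [c for c in df.columns if c not in ("FID", "IID")]
    if not value_cols:
        raise ValueError(f"{path}: no phenotype column after FID/IID")
    col = column if column is not None else value_cols[0]
    if col not in df.columns:
        raise KeyError(f"{path}: no column named {col!r} (have {value_cols})")
    aligned = _align(df, source, path)
    raw = aligned[col]
    values = np.full(source.n, np.nan)
    for i, v in enumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) in PHENO_MISSING_CODES:
            continue
        try:
            values[i] = float(v)
        except ValueError:
            line = i + 1
            raise ValueError(f"{path}: non-numeric phenotype {v!r} for sample line {line}")
    keep = np.flatnonzero(np.isfinite(values))
    n_missing = source.n - keep.size
    if n_missing:
        logger.info("phenotype: %d of %d samples missing, dropped", n_missing, source.n)
    y = values[keep]
    sd = y.std()
    if keep.size < 2 or sd == 0:
        raise ValueError(f"{path}: phenotype {col!r} has zero variance after alignment")
    y = (y - y.mean()) / sd
    return Phenotype(values=y, sample_indices=keep, n_missing=n_missing)


def read_covariates(
    path: str | Path, source: GenotypeSource, sample_indices: np.ndarray | None = None
) -> tuple[np.ndarray, list[str]]:
    """Read a multi-column covariate table aligned to (a subset of) FAM order.

    Every requested sample must have a complete row; a missing or
    non-numeric cell is an error naming its location.
    """
    df = _read_keyed_table(path)
    labels = [c for c in df.columns if c not in ("FID", "IID")]
    aligned = _align(df, source, path)
    if sample_indices is None:
        sample_indices = np.arange(source.n)
    out = np.empty((len(sample_indices), len(labels)))
    for j, col in enumerate(labels):
        vals = aligned[col].to_numpy()[sample_indices]
        for i, v in enumerate(vals):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                s = source.samples[sample_indices[i]]
                raise ValueError(f"{path}: missing covariate {col!r} for sample {s.fid} {s.iid}")
            try:
                out[i, j] = float(v)
            except ValueError:
                s = source.samples[sample_indices[i]]
                raise ValueError(
                    f"{path}: non-numeric covariate {col!r}={v!r} for sample {s.fid} {s.iid}"
                )
    return out, labels
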