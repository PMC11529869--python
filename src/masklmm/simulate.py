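"""Mosaic-chromosome genotype simulator with GCTA-style traits.

Synthetic individuals are built by concatenating fixed-length marker
segments (default 2000 variants) copied from a founder panel: unrelated
individuals draw every segment from a uniformly random founder, related
individuals draw only from a small private subset of founders, so fewer
ancestors per individual means higher relatedness.  Founders themselves are
synthesized under the Balding-Nichols model: an ancestral frequency
p ~ U(0.05, 0.5) per marker, per-population frequencies
Beta(p(1-F)/F, (1-p)(1-F)/F) at a chosen FST, and hard-call dosages
Binomial(2, p_pop).

Quantitative traits follow the GCTA simulation scheme: a random subset of
polymorphic markers is causal, effects are N(0, 1) on normalized dosages,
and environmental noise is scaled so the genetic fraction of phenotypic
variance matches the requested heritability.  Binary traits threshold the
quantitative liability at the empirical (1 - prevalence) quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .plinkio import SampleRecord, VariantRecord, write_bed

logger = logging.getLogger("masklmm")


@dataclass(frozen=True)
class SimulationSpec:
    n_samples: int = 1000
    m_markers: int = 10000
    n_founders: int = 100
    segment_len: int = 2000
    n_populations: int = 2
    fst: float = 0.01
    related_fraction: float = 0.0
    ancestors_per_related: int = 2
    n_causal: int = 25
    h2: float = 0.5
    trait_kind: str = "quantitative"  # {"quantitative", "binary"}
    prevalence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.segment_len < 1:
            raise ValueError("segment_len must be >= 1")
        if self.n_populations not in (1, 2):
            raise ValueError("n_populations must be 1 or 2")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must lie in [0, 1), got {self.fst}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must lie in [0, 1], got {self.h2}")
        if not 0.0 <= self.related_fraction <= 1.0:
            raise ValueError("related_fraction must lie in [0, 1]")
        if self.ancestors_per_related < 1:
            raise ValueError("ancestors_per_related must be >= 1")
        if self.related_fraction > 0 and self.ancestors_per_related > self.n_founders:
            raise ValueError("ancestors_per_related exceeds the founder count")
        if self.n_causal > self.m_markers:
            raise ValueError("n_causal exceeds the marker count")
        if self.trait_kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class TraitTruth:
    causal_indices: np.ndarray
    effects: np.ndarray
    genetic_values: np.ndarray
    noise: np.ndarray
    phenotype: np.ndarray
    realized_h2: float
    liability: np.ndarray | None = None  # quantitative scale for binary traits


def make_founders(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Founder dosage matrix (n_founders x m) and per-population frequencies.

    Returns (dosages, pop_freqs) with pop_freqs of shape
    (n_populations, m).  Founders are split evenly across populations.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.m_markers
    p_anc = rng.uniform(0.05, 0.5, size=m)
    if spec.fst > 0:
        F = spec.fst
        a, b = p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F
        pop_freqs = rng.beta(a, b, size=(spec.n_populations, m))
    else:
        pop_freqs = np.tile(p_anc, (spec.n_populations, 1))
    pop_of = np.arange(spec.n_founders) % spec.n_populations
    dosages = rng.binomial(2, pop_freqs[pop_of]).astype(np.int8)
    return dosages, pop_freqs


def segment_bounds(m: int, segment_len: int) -> list[tuple[int, int]]:
    """Half-open [lo, hi) marker intervals of length segment_len (last may be shorter)."""
    return [(lo, min(lo + segment_len, m)) for lo in range(0, m, segment_len)]


def founder_populations(spec: SimulationSpec) -> np.ndarray:
    """Population label of each founder (founders split evenly)."""
    return np.arange(spec.n_founders) % spec.n_populations


def individual_populations(spec: SimulationSpec) -> np.ndarray:
    """Population label of each simulated individual (split evenly)."""
    return np.arange(spec.n_samples) % spec.n_populations


def mosaic_individuals(
    founders: np.ndarray, spec: SimulationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble n individuals segment-by-segment from the founder panel.

    Mosaics are built within ancestral populations: individual i belongs to
    population i mod n_populations and copies segments only from founders
    of that population (falling back to the whole panel if a population has
    no founders).  Unrelated individuals draw each segment from a uniformly
    random eligible founder.  Related individuals form a sibship per
    population: every related individual of a population draws its segments
    from that population's shared ancestor subset of size
    ``ancestors_per_related``, so members of a sibship overlap heavily.

    Returns (dosages, ledger); ledger[i, s] is the founder supplying
    segment s of individual i, so the matrix can be replayed exactly.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_f, m = founders.shape
    bounds = segment_bounds(m, spec.segment_len)
    n = spec.n_samples
    f_pop = np.arange(n_f) % spec.n_populations
    pools, subsets = [], []
    for pop in range(spec.n_populations):
        pool = np.flatnonzero(f_pop == pop)
        if pool.size == 0:
            pool = np.arange(n_f)
        pools.append(pool)
        size = min(spec.ancestors_per_related, pool.size)
        subsets.append(rng.choice(pool, size=size, replace=False))
    i_pop = individual_populations(spec)
    n_related = int(round(spec.related_fraction * n))
    ledger = np.empty((n, len(bounds)), dtype=np.int64)
    for i in range(n):
        pool = pools[i_pop[i]] if i < n - n_related else subsets[i_pop[i]]
        ledger[i] = rng.choice(pool, size=len(bounds))
    dosages = np.empty((n, m), dtype=np.int8)
    for s, (lo, hi) in enumerate(bounds):
        dosages[:, lo:hi] = founders[ledger[:, s], lo:hi]
    return dosages, ledger


def _normalized(dosages: np.ndarray, cols: np.ndarray) -> np.ndarray:
    g = dosages[:, cols].astype(float)
    p = g.mean(axis=0) / 2.0
    return (g - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def simulate_trait(dosages: np.ndarray, spec: SimulationSpec) -> TraitTruth:
    """GCTA-style trait on top of a dosage matrix.

    Causal markers are sampled uniformly among polymorphic markers, effects
    are N(0, 1) on normalized dosages, and the noise variance is set from
    the realized genetic variance so that var(g) / var(y) targets h2.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n, m = dosages.shape
    poly = np.flatnonzero(dosages.astype(float).var(axis=0) > 0)
    if spec.n_causal > poly.size:
        raise ValueError(f"{spec.n_causal} causal markers requested, only {poly.size} polymorphic")
    causal = np.sort(rng.choice(poly, size=spec.n_causal, replace=False))
    effects = rng.standard_normal(spec.n_causal)

    if spec.h2 == 0.0:
        g = np.zeros(n)
        e = rng.standard_normal(n)
    else:
        W = _normalized(dosages, causal)
        g = W @ effects
        var_g = g.var()
        if spec.h2 == 1.0:
            e = np.zeros(n)
        else:
            sd_e = np.sqrt(var_g * (1.0 - spec.h2) / spec.h2)
            e = rng.normal(0.0, sd_e, size=n)
    y = g + e
    var_y = y.var()
    realized = float(g.var() / var_y) if var_y > 0 else 0.0

    liability = None
    if spec.trait_kind == "binary":
        liability = y
        n_cases = int(np.floor(spec.prevalence * n))
        order = np.argsort(-y, kind="stable")
        binary = np.zeros(n)
        binary[order[:n_cases]] = 1.0
        y = binary
    return TraitTruth(
        causal_indices=causal,
        effects=effects,
        genetic_values=g,
        noise=e,
        phenotype=y,
        realized_h2=realized,
        liability=liability,
    )


def default_samples(n: int, populations: np.ndarray | None = None) -> list[SampleRecord]:
    """Synthetic FAM records; the FID carries the population label."""
    width = len(str(n))
    if populations is None:
        populations = np.zeros(n, dtype=int)
    return [
        SampleRecord(fid=f"P{populations[i] + 1}", iid=f"I{i + 1:0{width}d}")
        for i in range(n)
    ]


def default_variants(m: int) -> list[VariantRecord]:
    return [
        VariantRecord(chrom="1", id=f"snp{j + 1}", cm=0.0, bp=j + 1, a1="A", a2="G")
        for j in range(m)
    ]


def write_dataset(
    dosages: np.ndarray,
    truth: TraitTruth,
    spec: SimulationSpec,
    prefix: str | Path,
    ledger: np.ndarray | None = None,
) -> None:
    """Write BED/BIM/FAM, phenotype TSV and causal-truth TSV (plus ledger)."""
    prefix = Path(prefix)
    n, m = dosages.shape
    samples = default_samples(n, individual_populations(spec))
    variants = default_variants(m)
    write_bed(dosages.astype(np.int8), variants, samples, prefix)
    with open(f"{prefix}.pheno", "w") as fh:
        fh.write("FID\tIID\tTRAIT\n")
        for s, y in zip(samples, truth.phenotype):
            fh.write(f"{s.fid}\t{s.iid}\t{y:.10g}\n")
    with open(f"{prefix}.truth", "w") as fh:
        fh.write("SNP\tINDEX\tEFFECT\n")
        for idx, eff in zip(truth.causal_indices, truth.effects):
            fh.write(f"{variants[idx].id}\t{idx}\t{eff:.10g}\n")
    if ledger is not None:
        np.savetxt(f"{prefix}.ledger", ledger, fmt="%d", delimiter="\t")
    logger.info("simulated dataset written to %s.{bed,bim,fam,pheno,truth}", prefix)


def simulate_dataset(spec: SimulationSpec) -> tuple[np.ndarray, TraitTruth, np.ndarray]:
    """Founders -> mosaic individuals -> trait; returns (dosages, truth, ledger)."""
    founders, _ = make_founders(spec)
    dosages, ledger = mosaic_individuals(founders, spec)
    truth = simulate_trait(dosages, spec)
    logger.info(
        "simulated %d individuals x %d markers (%d founders, %d causal, target h2=%.2f, "
        "realized h2=%.3f)",
        spec.n_samples, spec.m_markers, spec.n_founders, spec.n_causal, spec.h2,
        truth.realized_h2,
    )
    return dosages, truth, ledger
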