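# Methods

## Model

For n individuals genotyped at m markers, the phenotype vector y is modelled
as

    y = Xβ + Zu + e,    u ~ N(0, σ_u² I_m),    e ~ N(0, σ_e² I_n),

with Z the column-normalized genotype matrix, X a matrix of k covariates
(intercept, ancestry principal components, user covariates) and β their
fixed effects. Marginalizing u gives y ~ N(Xβ, σ_g² H_τ) with
H_τ = (1/m) Z Zᵀ + τ I and τ = σ_e²/σ_g²; (1/m) Z Zᵀ is the genetic
relationship matrix (GRM) on normalized genotypes and narrow-sense
heritability is h² = σ_g²/(σ_g²+σ_e²) = 1/(1+τ). Per-marker association is
tested with the generalized-least-squares score statistic
χ² = (z̃ᵀV⁻¹ỹ)²/(z̃ᵀV⁻¹z̃), V = σ̂_g² H_τ̂, referred to χ²₁, where z̃ and ỹ
are the tested column and the response after projecting out X under the
V⁻¹ inner product. Residualizing both sides is the standard GLS treatment;
it reduces to the bare formula when X is empty.

## Sketching

Both dimensions are compressed by Gaussian random projections before any
fitting: S₁ ∈ ℝ^{s₁×n} acts on samples, S₂ ∈ ℝ^{m×s₂} on markers (inside
the GRM only). Entries are i.i.d. N(0, 1/s₁) and N(0, 1/s₂), so inner
products are preserved in expectation and concentrate at
Johnson–Lindenstrauss rates. The pipeline computes Z_s₁ = S₁Z, y_s₁ = S₁y
and K = S₁ZS₂S₂ᵀZᵀS₁ᵀ in streaming marker blocks: per block b,
B += (S₁Z_b)·S₂[b, :], then K = BBᵀ — symmetric and positive semidefinite
by construction, and the full genotype matrix is never held in memory.

Three design choices around the sketch deserve explanation:

**Counter-based generation.** Sketch entries are generated per input index
from a Philox stream keyed by (seed, index). Any index range therefore
materializes identically regardless of block size or request order, which
is what makes the streamed products bit-reproducible and
partition-invariant.

**Row orthonormalization of S₁ (pipeline default).** For Gaussian noise
e ~ N(0, σ_e²I), the raw sketched residual S₁e has covariance σ_e²·S₁S₁ᵀ —
a Wishart matrix whose eigenvalues spread by ±2√(s₁/n) — while the model's
τI term assumes white noise. At aggressive sketching (s₁/n = 0.1) this
mismatch inflates the null scan badly (genomic inflation ≈ 1.4 in our
desk-scale experiments). The pipeline therefore replaces S₁ by L⁻¹S₁ with
L = chol(S₁S₁ᵀ): the rows become exactly orthonormal, the sketched noise is
exactly white, and the model form holds without approximation. The row
space — hence the information retained — is unchanged. The raw operator
remains available (`make_sketch`) and is what the distributional unit tests
exercise.

**Identity at full dimension.** A resolved sketch dimension equal to the
data dimension yields the identity operator rather than a square Gaussian
projection: projecting onto as many random directions as the space has
dimensions reduces nothing and would only inject noise. This makes the
fraction-1.0 limit exactly the unsketched computation, which is also what
enables the oracle-equivalence tests against a brute-force LMM.

Default sketch sizes are s₁ = ⌈0.1·n⌉ and s₂ = ⌈0.5·m⌉, both overridable as
fractions or absolute counts.

## Covariates

The top q = 10 (default) principal components of the column-centered Z_s₁
serve as ancestry covariates; they are computed exactly from the
eigendecomposition of the small s₁×s₁ Gram matrix, with signs fixed
deterministically. Because the model lives in sketched space, the intercept
and any user covariates are pushed through the same S₁, so every column of
X is the sketch of its original-space counterpart. The assembled X must be
full column rank; the first offending column is named otherwise.

## Variance components

With the eigendecomposition K = UΛUᵀ (computed once; negative eigenvalues
clipped at zero), H_τ is diagonal in the rotated basis for every τ, so each
profile-likelihood evaluation costs O(s₁k²). β and σ_g² are profiled out
analytically; writing D = diag(λᵢ/m + τ), ỹ = Uᵀy_s₁, X̃ = UᵀX:

    β̂ = (X̃ᵀD⁻¹X̃)⁻¹X̃ᵀD⁻¹ỹ,  r = ỹ − X̃β̂,  σ̂_g² = rᵀD⁻¹r / dof,

with dof = s₁ (ML) or s₁−k (REML), and the REML objective carries the usual
−½ log det(X̃ᵀD⁻¹X̃) term. The remaining one-dimensional objective is
maximized in θ = log τ (positivity for free) by Newton's method with
analytic first and second derivatives (envelope theorem for the moving β̂),
starting from τ = 1, with step halving to guarantee ascent. Convergence is
declared at |Δθ| < 10⁻⁶ or |dℓ/dθ| < 10⁻⁶ (both configurable); on
non-convergence a golden-section search over θ ∈ [log 10⁻⁶, log 10⁶] takes
over. After convergence a coarse 129-point grid guards against
multimodality — on small instances with a full-rank K the profile can have
a spurious τ→0 basin that fits the response exactly — and a few final
Newton steps drive the gradient to roundoff, so the reported optimum
matches a dense grid-plus-golden-section oracle to ~10⁻¹³ in
log-likelihood.

**ML vs REML.** Both are implemented; the pipeline and CLI default to REML.
At biobank scale the two are indistinguishable, but at desk scale
(s₁ ≈ 100, k ≈ 11) ML's division by s₁ rather than s₁−k shrinks σ̂ by
~k/s₁ and inflates every χ² by the inverse factor — enough to push null
type-I error at α = 0.05 visibly above its binomial band. REML centres the
null scan (λ_GC ≈ 0.96, type-I ≈ 0.045 in our calibration experiments) and
is the convention of the standard variance-component GWAS tools.

## Association scan

V⁻¹ is applied through the stored spectrum
(V⁻¹x = U diag(1/(σ̂_g²(λᵢ/m+τ̂))) Uᵀx), so the whole scan is a handful of
dense s₁-sized products. Markers whose residualized self-inner-product
falls below 10⁻¹² are reported untestable (χ² = 0, p = 1, flagged). Raw
p-values only; no multiple-testing correction and no significance filter is
applied by the tool.

## Simulator

The generator emulates the construction used for the package's validation
experiments: founder panels stand in for real genetically distinct groups,
and synthetic individuals are mosaics of founder segments.

- **Founders.** Ancestral allele frequencies p_j ~ U(0.05, 0.5);
  per-population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) at F = F_ST
  (two identical populations at F = 0); hard-call dosages Binomial(2, p).
  Founders and individuals split evenly across populations.
- **Mosaics.** The genome is cut into consecutive segments of 2000 variants
  (default; the last segment may be shorter). Each unrelated individual
  draws every segment from a uniformly random founder *of its own
  population*; related individuals form one sibship per population, drawing
  segments only from a shared ancestor subset of size
  `ancestors_per_related` — fewer ancestors, higher relatedness. A ledger
  records the source founder of every segment, so the matrix replays
  exactly.
- **Traits.** GCTA-style: causal markers drawn uniformly among polymorphic
  markers, effects N(0, 1) on normalized dosages, noise variance set from
  the realized genetic variance to hit the target h² (h² = 0 gives pure
  noise, h² = 1 no noise). Binary traits threshold the liability at its
  empirical (1−prevalence) quantile, so the case count is exactly
  ⌊prevalence·n⌋.

What the simulator does **not** emulate: within-segment recombination and
map-based LD (markers are independent in the founders; LD arises only from
segment co-inheritance), imputation dosages, genotyping error, and
ascertainment. Tests passing on these data therefore demonstrate the
correctness and calibration of the machinery, not robustness to real-data
artefacts such as fine-scale LD or array batch effects.

## Problem sizes used in validation

The acceptance-style experiments run at desk scale, chosen so the full
suite completes in minutes on one CPU: heritability recovery averages 20
replicates at n = 500, m = 5,000 (identity sample sketch, 50% marker
sketch); null calibration averages 25 pure-noise replicates at n = 1,000,
m = 5,000 under default sketches — averaging matters because with s₁ = 100
all markers share a 100-dimensional sketched response, making single-run
λ_GC fluctuate by ±15%; the power/sketch trade-off uses n = 2,000,
m = 3,000 with 100-marker segments, preserving the many-segments-per-genome
geometry of the large simulated cohorts it scales down (with only one or
two segments per genome, mosaic relatedness collapses the effective sample
size and every method loses power).

## Numerical conventions and edge cases

- Genotype normalization: missing hard calls imputed to the marker mean
  2p̂; columns centered by 2p̂ and scaled by √(2p̂(1−p̂)); markers with
  MAF < 0.01 (configurable) or zero variance are dropped before sketching.
- BED dialect: PLINK 1 SNP-major only; the two-bit code counts the A1
  allele (00→2, 10→1, 11→0, 01→missing). BIM positions stay 1-based;
  internal marker intervals are 0-based half-open.
- Phenotypes: −9 and NA are missing; samples with missing phenotype are
  dropped (logged) before sketching; the retained response is centered and
  scaled to unit variance. A constant phenotype is an error.
- Spectrum: eigenvalues clipped at zero (count logged); σ̂_g² = 0 makes V
  singular and raises rather than silently scanning with the null model.
- Ties in the binary-trait threshold are broken by stable sort order.

## Known limitations

No leave-one-chromosome-out (LOCO) GRM: the tested marker contributes to K,
and the resulting proximal contamination mildly deflates test statistics —
visible at desk scale as null type-I error a few thousandths below α. No
saddlepoint or logistic correction for binary traits (analyzed as 0/1
quantitative). Hard-call genotypes only (no BGEN/VCF dosages, no PGEN). One
random effect; no AI-REML or EM alternatives.
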