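# Methods

This note documents the statistical models implemented in `pleiogene`, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish.

## Gene-based association

For a gene containing m SNPs with marginal Z-scores z = (z₁…z_m) and local
LD correlation matrix R, the statistic is S = Σⱼ zⱼ². Under the null
z ~ N(0, R), so S is distributed as Σᵢ λᵢ χ²₁ with λᵢ the eigenvalues of R.
This is the sum-of-chi-squares ("SNP-wise mean"-type) gene model; the
covariate-adjusted regression variants some gene-analysis tools offer are
out of scope.

Tail probabilities are computed by numerical inversion of the
characteristic function (Imhof's integral),

p = 1/2 + (1/π) ∫₀^∞ sin θ(u) / (u·ρ(u)) du,

evaluated as a vectorized midpoint lattice sum. The step is
Δ = 4π / (|s| + μ + 40σ) with μ = Σλᵢ and σ² = 2Σλᵢ², which places the
aliasing images of the distribution ≈ 40 standard deviations beyond the
evaluation point; the sum terminates when an integration-by-parts bound on
the oscillatory remainder, (2/π)·env(U)/max(s, 1), falls below 1e-10.
Validated against an exact smooth-convolution computation for m = 2 the
lattice agrees to ~1e-14; against 10⁶-draw Monte Carlo it agrees within
Monte-Carlo error on random AR(1) fixtures. Exact reductions are used when
all eigenvalues coincide (single SNP, identity LD: a scaled chi-square),
and a Satterthwaite moment-matched scaled chi-square serves as the fallback
for non-convergent cases and for tails below 1e-10 where the oscillatory
integral loses relative accuracy (for the equal-eigenvalue cases that
dominate there, it is exact). Eigenvalues below −1e-8 are rejected as
non-PSD; roundoff negatives above that are clipped to zero.

The gene p-value is converted to a signed normal score
z_gene = sign · Φ⁻¹(1 − p/2) with sign = +1 iff Σⱼ βⱼ·MAFⱼ ≥ 0 (an exact
zero resolves to +1; the tie rule is arbitrary but fixed). The two-sided
conversion is used because the sign is attached explicitly; a one-sided
Φ⁻¹(1 − p) would double-count the direction. p is floored at 1e-300 before
inversion. SNP-to-gene assignment is strictly positional with no window
padding (a `window` extension would be straightforward; positions are
1-based inclusive throughout).

## Composite-null pleiotropy test

For a pair of traits the hypothesis "this gene is pleiotropic" has a
composite null: H00 (neither trait associated) ∪ H10 ∪ H01 (exactly one).
The test statistic is the product T = z₁*·z₂* of the de-correlated gene
scores. Under independent zero-mean normals with scales s₁, s₂ the product
density is f(w) = K₀(|w| / (s₁s₂)) / (π s₁ s₂); tails are computed from the
scaling identity prob(t, s₁, s₂) = prob(t/(s₁s₂), 1, 1) with adaptive
quadrature of K₀ (exponentially scaled beyond t = 1 to avoid underflow).

The three sub-null p-values are p00 = P(|XY| ≥ |T|) with unit scales,
p10 with X scaled by σ₁ and p01 with Y scaled by σ₂, where σₖ² is the
marginal variance of trait k's gene Z-scores floored at 1 — the
overdispersion of a polygenic trait's Z is precisely what the
one-trait-associated sub-nulls must absorb. The variance is deliberately
taken over **all** genes (no signal trimming): trimming would shrink σ²
toward 1 and make the H10/H01 tails anti-conservative. The
intersection–union p-value is max(p00, p10, p01): the composite null is
rejected only when every sub-null is. This construction is self-contained
and validated by its own simulation gates (empirical size at α = 0.05
within Monte-Carlo error of, or below, nominal under H00, H10 and H01).

**De-correlation.** Overlapping GWAS samples correlate the two traits'
Z-scores even at null genes. The correlation ρ_z is estimated genome-wide
after excluding genes with min(p₁, p₂) < 1e-4 (configurable) so true signal
does not inflate the estimate, and removed with the symmetric inverse
square root of [[1, ρ], [ρ, 1]]. |ρ_z| ≥ 0.99 is rejected as untestable.
A simulation gate demonstrates that skipping this step inflates type-I
error under a pure-overlap null while the whitened test stays calibrated.

**Comparators.** The direct-FDR method intersects the per-trait BH
discoveries; the maximum-P method applies BH to per-gene max(p₁, p₂). On
architectures with both shared and trait-specific causal genes the
composite-null test dominates both at matched FDR (the package's power
gate), mirroring the qualitative ordering reported for gene-level scans of
psychiatric GWAS. FDR is controlled within each trait pair; BY (with its
harmonic-number penalty) is reserved for per-SNP heterogeneity p-values,
where local LD makes dependence arbitrary.

**Overall-pleiotropy LRT.** Gene p-value pairs are modelled as a
four-component mixture over association states, null density uniform and
alternative density α·p^(α−1) (0 < α < 1) per trait. The constrained model
imposes independence, π₁₁ = (π₁₀+π₁₁)(π₀₁+π₁₁), under which the likelihood
factorizes into two marginal two-component mixtures — the implementation
exploits this. The statistic 2·(ll_full − ll_constrained) is referred to χ²₁
(one constraint). EM runs in log space (p-values to 1e-300 would otherwise
overflow p^(α−1)), capped at 5000 iterations with tolerance 1e-9 on the
log-likelihood. Exactly-uniform inputs leave the likelihood flat along a
(q, α→1) ridge on which the mixture is observationally uniform; a fit
whose per-iteration improvement has fallen below 1e-4 at the cap is
accepted as converged, since residual creep at that scale is invisible
against χ²₁ quantiles. Null calibration (rejection ≈ 0.05 over 200
replicates) is part of the test suite.

## LD score regression

ℓⱼ = Σₖ r̃²ⱼₖ over SNPs within a 10 Mb window (same-block under block LD),
with the bias-adjusted estimator r̃² = r² − (1 − r²)/(n_ref − 2) for a
finite reference panel (n_ref = 503 by default; 0 disables the adjustment
when population correlations are exact, as in simulation). The univariate
regression E[χ²ⱼ] = intercept + (N·h²/M)·ℓⱼ uses weights
1/(ℓⱼ·(1 + N·h²·ℓⱼ/M)²) iterated twice from an OLS start; the bivariate
regression of z₁ⱼz₂ⱼ on ℓⱼ uses the analogous product weights, and
r_g = ρ_g/√(h²₁·h²₂). The genetic-covariance intercept estimates the
sample-overlap term ρ·Ns/√(N₁N₂). Standard errors come from a
delete-a-block jackknife over 200 contiguous SNP blocks (block count
configurable, reduced with a warning when SNPs are scarce); the r_g
jackknife re-estimates both heritabilities and the covariance slope per
deleted block. Non-positive heritability leaves r_g undefined (flagged);
|r_g| > 1.25 is flagged but reported. λ_GC = median(z²)/0.4549.

At desk scale (M ~ 10⁴ SNPs rather than ~10⁷) intercept and slope separate
weakly if LD scores vary little, so the default synthetic reference draws
each block's AR(1) decay from a range (0.1–0.9), spreading ℓ over roughly
1–9 as heterogeneous real LD does. Trait clustering uses distance 1 − r_g
with average linkage (missing entries imputed as 0 with a warning); traits
are sorted internally so the partition is invariant to input order.

## Mendelian randomization

Instruments are selected by greedy clumping: candidates with p < 1e-5
ranked by ascending p (ties by position, then id); the best SNP is kept and
candidates within 10 Mb **and** r² > 0.001 of it are discarded. The relaxed
threshold (rather than 5e-8) buys instrument counts for modestly powered
traits at the cost of pleiotropy risk, which the screen counteracts by
dropping instruments whose outcome p-value falls below a Bonferroni bound
α/J with J the post-clumping instrument count.

Estimators on the per-SNP ratios β̂ⱼ = b_yⱼ/b_xⱼ with weights
wⱼ = b_xⱼ²/s_yⱼ²:

- **IVW** — weighted mean; multiplicative random-effects SE
  √(max(1, Q/(J−1)) / Σw) (fixed-effect available by flag). With equal
  weights this is exactly the simple mean of ratios, and the fixed-effect
  version equals WLS of b_y on b_x through the origin.
- **Weighted median** — interpolated weighted median of the ratios;
  consistent while valid instruments carry > 50% of the weight; SE by
  seeded parametric bootstrap (default 10⁴ resamples).
- **MR-Egger** — WLS of b_y on b_x with a free intercept after orienting
  b_x ≥ 0; the intercept estimates directional pleiotropy, the slope the
  causal effect; SEs carry a multiplicative overdispersion factor floored
  at 1 and intercept p-values use t with J − 2 degrees of freedom.

Diagnostics per relationship: per-SNP F = (b_x/s_x)², total variance
explained Σ 2·MAF(1−MAF)·b_x² on the standardized-trait scale. The screen
runs a full design — one-sided childhood→adulthood plus all ordered
adulthood pairs — with BH FDR computed jointly over all IVW p-values
(per-analysis FDR available), bidirectional-significance flags, and the
IVW/weighted-median concordance over significant findings.

## Synthetic data generator

The generator emulates the statistical structure the estimators assume;
its defaults are the package's study conditions.

- **LD**: block-diagonal, AR(1) within blocks (r_jk = ρ^|j−k|, always
  positive definite; per-block ρ drawn from a range by default). Blocks of
  50 SNPs, 20 blocks per surrogate chromosome, MAF uniform on (0.05, 0.5),
  non-palindromic alleles. No MAF–LD coupling, no sex chromosomes, no
  real-genotype resampling.
- **Summary statistics**: per block, joint Z for two traits drawn
  multivariate normal with mean (√N₁·R·b₁, √N₂·R·b₂), per-trait covariance
  R and cross-trait covariance ρ_overlap·R — the overlap term reproduces
  correlated null Z-scores. Reported effects are β̂ = z·se with
  se = 1/√(2N·MAF(1−MAF)); standardized effects are rescaled so
  Σb² = h² exactly per replicate.
- **Architecture**: causal genes drawn per trait (fraction
  `prop_causal_genes`); a configurable fraction is a shared set whose
  effects correlate at r_g across traits, the rest are trait-specific.
  Per-SNP effects within causal genes are **independent by default**
  (`gene_effect_share = 0`): a dominant shared within-gene component
  violates the uncorrelated-effects assumption of LD score regression and
  inflates ĥ² several-fold at these block sizes, which the package's own
  recovery gates would (and did, during development) catch. Gene-level
  truth remains well defined — a causal gene is one whose SNPs carry
  effects — and the shared-component weight is exposed for users who want
  sign-coherent within-gene effects and do not need LDSC on the same data.
- **MR instruments**: exposure effects with random sign and magnitude
  uniform on [0.5, 1.5]·σ_x — bounded away from zero, as real instruments
  are after significance selection; near-null effects would otherwise be
  mis-oriented and wash out the Egger intercept. Direct (horizontal)
  effects α_j ~ N(directional, sd²) are applied on the
  exposure-increasing-allele orientation, the scale on which directional
  pleiotropy is defined and estimated. Balanced pleiotropy has
  directional = 0; a fraction of instruments can be made invalid with a
  fixed extra outcome effect.
- **Multi-trait sets with causality**: trait-specific sparse architectures
  plus an acyclic matrix of causal effects propagated through total
  effects, so an exposure's instruments show proportional outcome effects
  — the two-sample MR structure — while reverse-direction instruments do
  not.

What passing the synthetic gates shows: the estimators are calibrated and
recover their own generative parameters under the models they assume. What
it does not show: robustness to features of real GWAS the generator omits
— MAF-dependent architectures, LD-dependent effect sizes, assortative
mating and population stratification, case-control ascertainment, INDELs,
imputation error, genome-build mismatches.

## Problem sizes and numerical conventions

Validation runs use 10⁴–2.5×10⁴ SNPs, 1000–5000 genes of 5–10 SNPs, GWAS
sizes 2×10⁴–10⁵, 20 replicates for LDSC coverage gates and 200 for MR
recovery and LRT calibration; Monte-Carlo oracles use 10⁶ draws (gene
test) and 10⁷ (product-normal). These sizes were chosen so each gate's
Monte-Carlo error is small against the tolerance it checks. The power
study uses N = 20,000 and h² = 0.15 — a deliberately moderate-power regime
in which the methods separate; at saturation every method detects
everything and at very low power none detects anything.

Conventions: positions 1-based inclusive; MHC boundaries inclusive;
palindromic SNPs dropped rather than frequency-inferred; OR columns
converted by natural log at read time; MAF taken from the GWAS file (not
the panel) when both exist; all tables TSV with floats at 6 significant
digits; every random process takes an explicit integer seed and a root
seed expands through fixed offsets recorded in the run manifest.

## Known limitations

- The gene model is the sum-of-chi-squares variant only; which specific
  gene-analysis model a given published study used is generally not
  knowable from its text, and results can differ between variants.
- The product-normal sub-null construction with marginal-variance
  σ-estimation is one concrete realization of the composite-null test;
  other implementations make different internal approximations, so
  agreement is statistical (calibration and power), not numerical
  equivalence.
- Desk-scale LDSC (M ~ 10⁴) has weak slope/intercept separation; single
  replicates can show large intercept excursions even though coverage is
  correct across replicates.
- The MR outcome-association filter removes the strongest shared
  instruments and attenuates causal estimates toward zero when the planted
  effect is strong; this is the usual bias-variance trade of the filter,
  visible in the README example.
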