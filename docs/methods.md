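# Methods

## Model

Phenotypes are binary labels y ∈ {0,1}ⁿ, encoded as spins s = 2y − 1. Given
per-individual covariate vectors xᵢ (intercept, covariates, and the SNP
under test) and a fixed symmetric matrix of pairwise genetic similarities,
the joint distribution of all labels is a fully connected pairwise random
field

    P(y | X, A) = Z⁻¹ exp( Σᵢ sᵢ (w·xᵢ) + Σ_{i<j} A_{ij} sᵢ sⱼ ).

The pairwise term rewards phenotype agreement between genetically similar
individuals symmetrically (agreeing pairs gain +A_{ij}, disagreeing pairs
lose it), which is what lets the model absorb phenotype clustering along
ancestry and kinship lines instead of attributing it to the tested SNP.
The spin encoding is chosen over a {0,1} encoding because it makes the
pairwise potential symmetric under global label exchange; a {0,1}-coded
interaction would additionally shift each individual's field by its row
sum of A, which is absorbed by the intercept but obscures interpretation.

Z sums over all 2ⁿ configurations and is intractable beyond toy sizes, so
the model is fitted by maximum pseudo-likelihood: the product over
individuals of P(yᵢ | y₋ᵢ). Under the model this conditional is exactly
logistic,

    P(yᵢ = 1 | y₋ᵢ) = σ(2(w·xᵢ + rᵢ)),   rᵢ = Σ_{j≠i} A_{ij} sⱼ,

with Z cancelled. The negative log-pseudo-likelihood is a convex function
of w (a logistic-regression objective with per-individual offsets), so the
optimum is unique and initialization-independent. The factor 2 is a fixed
reparameterization: with A ≡ 0 the fitted weights are exactly half the
logistic-regression coefficients and all test statistics coincide.

## From similarities to couplings

Similarities are identity-by-state (IBS) allele-sharing fractions: at one
locus two genotypes g, g' ∈ {0,1,2} (minor-allele counts, treated as
unordered allele pairs) share (2 − |g − g'|)/2 of their alleles; averaging
over the loci observed in both individuals gives A ∈ [0,1]ⁿˣⁿ with unit
diagonal. Missing genotypes are handled pairwise-complete here, and
mean-imputed before the per-SNP standardization in the scan (the source
data conventions are silent on both; these are this package's choices).

Raw IBS cannot be used as coupling weights directly, for two measured
reasons:

1. **Baseline and row effects.** Human IBS sits on a large common baseline
   (≈0.7–0.8) plus per-individual row effects (a highly heterozygous
   individual shares at least one allele with everyone). Summed over
   hundreds of neighbours, the baseline saturates every conditional, and
   the row effects leak each individual's genotype composition into its
   offset, biasing every SNP test. Couplings are therefore the **Gower
   double-centered** similarities (row means, column means and grand mean
   removed; diagonal zeroed) — the standard similarity-to-kernel
   transform, retaining only relatedness in excess of the sample average.

2. **Scale.** A fully connected binary field with coupling matrix C is in
   a frozen (spontaneously ordered) phase once 2λ_max(C) > 1; centered IBS
   kernels have λ_max an order of magnitude above that, so unit-coefficient
   couplings put the model deep in the saturated regime where conditionals
   are step functions and inference degenerates. The scan therefore scales
   the neighbour field by a single scalar coefficient γ estimated from the
   data: γ is fitted **once per phenotype under the null model**
   (intercept + covariates + field, no SNP) and then held fixed as an
   offset γ·rᵢ for every SNP test. This mirrors mixed-model GWAS practice,
   where variance components are estimated once under the null and reused
   across the scan. Re-estimating γ jointly with each SNP is available
   (`coupling_scale="learned"`) but not the default: a coefficient on a
   phenotype-derived covariate re-fitted in the presence of each tested
   SNP lets the fit trade SNP weight against field weight test-by-test,
   which measurably inflates the null. A unit-coefficient offset
   (`coupling_scale="fixed"`) is kept for experiments where the couplings
   are known, e.g. data sampled from the field itself.

## Inference

At the pseudo-likelihood optimum ŵ, with πᵢ = σ(2(ŵ·xᵢ + offsets)):

- Hessian H = Σᵢ 4πᵢ(1−πᵢ) xᵢxᵢᵀ (symmetric PSD everywhere — convexity);
- per-individual scores gᵢ = 2(πᵢ − yᵢ)xᵢ, B = Σᵢ gᵢgᵢᵀ;
- sandwich Σ̂ = H⁻¹BH⁻¹ (pseudo-inverse with an untestable flag if H is
  numerically singular);
- Wald statistic (ŵ_snp / Σ̂_snp^½)² referred to χ² with 1 degree of
  freedom, two-sided, no multiple-testing correction in the core scan.

B uses per-individual score terms; cross-individual score covariances
(nonzero under the field) are omitted, which is accurate in the
weak-coupling regime the scan operates in and is the conventional sandwich
form. Optimization is damped Newton with backtracking by default (the
objective is convex; typically < 10 iterations); plain gradient descent
with learning rate η (default 0.01) is available and reaches the same
optimum. Convergence is declared at gradient max-norm ≤ 1e−8, capped at
500 iterations; exactly collinear design columns are dropped greedily with
the dropped indices reported, and monomorphic SNPs are flagged untestable
rather than silently removed. All probabilities are computed with
numerically stable log-logistic primitives; the brute-force partition
function (used only by oracles and tests) refuses n > 20.

## Complexity

The neighbour field r = A s costs O(n²) once per phenotype; the null-model
γ fit and each per-SNP fit touch O(n·p) per iteration with p the number of
design columns. An `OpCounter` records elements touched by the kernels so
the quadratic-once / linear-per-SNP structure is asserted by operation
counts, not wall clocks.

## Synthetic data

The generator emulates a structured human cohort:

- **Genotypes**: Balding–Nichols — ancestral frequency p ~ U(0.1, 0.9) per
  SNP; subpopulation frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), so F is
  F_ST; genotypes Binomial(2, p_sub). Within subpopulations, individuals
  are grouped into family blocks (default 6: two founders with explicit
  haplotype pairs, offspring inheriting one allele from each founder per
  locus). Defaults: n = 500, 4 subpopulations, F_ST = 0.1 — the structure
  of a multi-ethnic family study; panel of 3000 SNPs, several-fold the
  sample size, as in the real panels this mimics (similarities estimated
  from many more loci than individuals).
- **Phenotypes**: GLMM — random effect u ~ N(0, σ²K) with K the
  standardized kinship (Gower-centered IBS scaled to unit mean diagonal, so
  σ² is per-individual genetic liability variance; default σ² = 1), linear
  predictor β·(standardized SNP) + covariate terms + u, intercept solved by
  bisection so the mean of σ(η + c) hits the target prevalence (default
  0.5), labels Bernoulli. Evaluation protocols draw a **separate phenotype
  per tested SNP**, so each (SNP, phenotype) pair is an independent trial;
  sharing one phenotype across a panel makes the inflation factor of a
  single scan strongly seed-dependent, because all tests then share one
  random-effect draw.
- **Field-sampled data** (for parameter recovery): systematic-scan Gibbs
  with incrementally maintained neighbour field; couplings scaled
  spectrally subcritical (2λ_max = ν, default ν = 0.5), because above
  criticality the chain freezes into ordered modes and the sandwich
  asymptotics no longer describe the estimator. Recovery experiments fit
  with the true couplings fixed.

What the simulator does **not** emulate: linkage disequilibrium (SNPs are
independent given ancestry and pedigree), genotyping error, ascertainment,
sex chromosomes, non-random mating beyond the two-founder blocks. Passing
calibration and power checks on these data therefore demonstrates the
method's behaviour under stratification and relatedness, not under LD or
data-quality artifacts.

## Numerical and protocol choices

- Covariate standardization uses the population (divide-by-n) SD; constant
  columns become zeros and are reported. Ages are one-hot binned into five
  half-open ranges [lo, hi); bin edges are configuration (quintiles are a
  reasonable default).
- The χ²₁ null median is fixed at 0.45493642; λ is computed from Wald
  statistics directly rather than round-tripping through p-value tails.
  QQ expected quantiles use (k − 0.5)/n with pointwise Beta(k, n−k+1)
  95% bounds. ROC curves sweep all distinct p-values; AUC is the
  trapezoid integral and equals the Mann–Whitney pair probability up to
  tie handling.
- The evaluation panel includes the tested SNPs in the similarity matrix
  (as when a study computes IBS from the full genotyping array).
  Leave-one-SNP-out similarity was implemented and measured during
  development and does not change null calibration within Monte-Carlo
  error at the default panel/sample ratio, so the simpler fixed matrix is
  used.

## Known limitations

- The correction conditions on observed neighbour phenotypes rather than
  integrating over a latent random effect; with very few loci in the
  similarity panel relative to n, or with many phenotype-derived
  correction covariates, conditioning artifacts can bias per-SNP tests.
  The defaults (single prefit γ, panel several times n) are chosen to keep
  those artifacts below Monte-Carlo noise, as verified by the null
  calibration tests.
- The per-individual sandwich omits cross-score covariance; under strong
  coupling it understates variance. The subcritical regime used throughout
  is where the χ²₁ reference is accurate.
- The genomic inflation factor estimated from ~1000 tests has a
  Monte-Carlo standard deviation of roughly 0.07 even for a perfectly
  calibrated method; single-scan λ values should be read with that in
  mind.
- Binary phenotypes only; PLINK binary (.bed) input, LD pruning and
  permutation p-values are out of scope.
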