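# crfgwas

Genome-wide association testing with a pairwise conditional random field
over phenotypes, for case/control studies confounded by population
structure, family structure or cryptic relatedness.

## The problem and the model

In a structured cohort, a SNP can correlate with a binary phenotype simply
because both track ancestry or kinship, producing spurious associations.
Mixed-model methods absorb this through a genetic similarity matrix used as
the covariance of a random effect, at cubic cost in the number of
individuals n. `crfgwas` instead models the label vector y ∈ {0,1}ⁿ
jointly, as a fully connected binary random field conditioned on each
individual's SNP and covariates. With spins s = 2y − 1,

    P(y | X, A) ∝ exp( Σᵢ sᵢ (w·xᵢ)  +  Σ_{i<j} A_{ij} sᵢ sⱼ ),

where xᵢ is individual i's covariate/SNP vector, w the weights, and A_{ij}
a fixed pairwise genetic similarity — here identity-by-state (IBS) allele
sharing across the SNP panel, double-centered so only relatedness in excess
of the sample average couples two phenotypes. The partition function of
this model sums 2ⁿ terms, so fitting maximizes Besag's pseudo-likelihood
instead: each label's conditional given all others is an ordinary logistic

    P(yᵢ = 1 | y₋ᵢ) = σ( 2(w·xᵢ + γ rᵢ) ),    rᵢ = Σ_{j≠i} A_{ij} sⱼ,

so one precomputes the neighbour field r once per phenotype (O(n²)),
estimates the coupling coefficient γ once under the null model, and each
per-SNP fit is then a convex logistic problem with a fixed offset — linear
in n per iteration. SNP significance is a Wald χ²₁ test of the SNP weight
using the robust sandwich variance H⁻¹BH⁻¹ (pseudo-likelihood Hessian H,
score outer-product B). Calibration is summarized by the genomic inflation
factor λ = median(χ²)/0.4549 and power by ROC/AUC on simulated truths.

A Balding–Nichols + family-block genotype simulator and a GLMM phenotype
sampler (random effect u ~ N(0, σ²K), K the standardized kinship from IBS)
make the whole evaluation reproducible without any external data.

## Worked example

```python
from crfgwas.protocols import null_calibration_study, power_study

calib = null_calibration_study(n=200, panel_snps=1200, n_null=300, seed=7)
print(f"corrected scan:  lambda_GC = {calib['crf_lambda']:.3f}  (KS uniformity p = {calib['crf_ks_pvalue']:.3f})")
print(f"naive logistic:  lambda_GC = {calib['naive_lambda']:.3f}  (KS uniformity p = {calib['naive_ks_pvalue']:.2e})")

power = power_study(n=200, panel_snps=1200, reps=150, seed=7)
for beta in (0.1, 0.2, 0.5):
    print(f"AUC at SNP weight {beta}: {power['auc'][beta]:.3f}")
```

prints

```
corrected scan:  lambda_GC = 0.864  (KS uniformity p = 0.751)
naive logistic:  lambda_GC = 1.400  (KS uniformity p = 6.35e-03)
AUC at SNP weight 0.1: 0.491
AUC at SNP weight 0.2: 0.534
AUC at SNP weight 0.5: 0.858
```

Read: on 300 null SNPs from a structured cohort (4 subpopulations,
F_ST = 0.1, six-person families, genetic liability variance σ² = 1), plain
logistic regression is inflated (λ = 1.40, p-values non-uniform), while the
random-field scan is calibrated (λ ≈ 1, p-values uniform). Power to detect
a true SNP effect grows with the simulated weight; at n = 200 a weight of
0.5 is separated from the nulls with AUC 0.86 (at the default n = 500 it
exceeds 0.95).

The same pipeline is scriptable from the shell:

```sh
crfgwas simulate --n 500 --m 3000 --reps 50 --seed 17 --out bench/
crfgwas scan --geno bench/genotypes.tsv --pheno bench/pheno_0000.tsv \
             --sim bench/similarity.tsv --out bench/pheno_0000.results.tsv
crfgwas evaluate --results bench/ --truth bench/truth.json --out report.json
```

Estimator-style access (`sklearn` conventions) is available through
`crfgwas.PairwiseCRF` (fit / predict_proba / coef_ / sandwich_) and
`crfgwas.CRFGenomeScan` (fit → `results_` table).

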