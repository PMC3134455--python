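"""Structured-population genotype and mixed-model phenotype simulation.

Genotypes follow the Balding-Nichols construction: each SNP has an
ancestral frequency p ~ Uniform(0.1, 0.9); each subpopulation draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance
F p(1-p), so F plays the role of Wright's fixation index F_ST.  Within a
subpopulation, individuals are organised into family blocks: two founders
draw independent allele pairs from the subpopulation frequency and the
remaining block members are offspring, inheriting one allele from each
founder per locus.  This produces the two confounders the association model
must absorb — allele-frequency stratification between subpopulations and
excess allele sharing within families.

Phenotypes come from a generalized linear mixed model: a random effect
u ~ N(0, sigma^2 K) with K the standardized kinship kernel derived from
the IBS similarity matrix (unit mean diagonal, so sigma^2 is the
per-individual genetic liability variance), a linear predictor
eta_i = beta * snp_i + covariate terms + u_i, an intercept c solved so the
mean of sigma(eta + c) hits the target prevalence, and Bernoulli labels
y_i ~ Bernoulli(sigma(eta_i + c)).  Because u covaries as K, phenotypes
cluster along ancestry and family lines even when beta = 0, which is
exactly the false-positive-generating regime the random field corrects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .datatypes import CovariateMatrix, GenotypeMatrix, PhenotypeVector, SimilarityMatrix
from .similarity import compute_ibs, standardize_genotype_column, standardized_kinship

__all__ = [
    "PopulationConfig",
    "GlmmConfig",
    "SyntheticDataset",
    "simulate_genotypes",
    "solve_prevalence_offset",
    "simulate_phenotypes_glmm",
    "build_benchmark",
]


@dataclass
class PopulationConfig:
    """Study-design knobs for the genotype simulator.

    Defaults mimic a structured human cohort: four subpopulations at
    F_ST = 0.1 with six-person families (two founders, four offspring),
    and a marker panel several times the sample size so pairwise
    similarities are estimated from many more loci than individuals.
    """

    n_individuals: int = 500
    n_snps: int = 3000
    n_subpops: int = 4
    fst: float = 0.1
    family_block_size: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if self.family_block_size < 1:
            raise ValueError("family_block_size must be >= 1")
        if self.n_individuals < 2 or self.n_snps < 1:
            raise ValueError("need >= 2 individuals and >= 1 SNP")


@dataclass
class GlmmConfig:
    """Phenotype-model knobs: SNP effect, random-effect variance, prevalence."""

    snp_weight: float = 0.0
    variance: float = 1.0
    target_prevalence: float = 0.5
    covariate_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must be in (0, 1)")


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    covariates: CovariateMatrix | None
    phenotypes: PhenotypeVector
    similarity: SimilarityMatrix
    truth_beta: dict[str, float] = field(default_factory=dict)
    tested_snp: str | None = None


def simulate_genotypes(cfg: PopulationConfig) -> GenotypeMatrix:
    """Draw a structured genotype matrix; bit-reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    n, m, S = cfg.n_individuals, cfg.n_snps, cfg.n_subpops
    F = cfg.fst

    p_anc = rng.uniform(0.1, 0.9, size=m)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    p_sub = rng.beta(a, b, size=(S, m))  # one frequency row per subpopulation

    # round-robin remainder: subpopulation sizes differ by at most one
    subpop = np.arange(n) % S
    subpop.sort()

    values = np.empty((n, m), dtype=np.int8)
    i = 0
    while i < n:
        s = subpop[i]
        block = min(cfg.family_block_size, int(np.sum(subpop[i:] == s)))
        p = p_sub[s]
        if block <= 2 or cfg.family_block_size <= 2:
            for k in range(block):
                values[i + k] = rng.binomial(2, p).astype(np.int8)
        else:
            # founders carry explicit haplotype pairs; offspring inherit one
            # allele from each founder, independently per locus
            founders = rng.random((2, 2, m)) < p  # (parent, haplotype, locus)
            values[i] = founders[0].sum(axis=0).astype(np.int8)
            values[i + 1] = founders[1].sum(axis=0).astype(np.int8)
            for k in range(2, block):
                from_mother = founders[0][rng.integers(0, 2, size=m), np.arange(m)]
                from_father = founders[1][rng.integers(0, 2, size=m), np.arange(m)]
                values[i + k] = (from_mother + from_father).astype(np.int8)
        i += block

    ind_ids = np.array([f"ind{k}_s{subpop[k]}" for k in range(n)], dtype=object)
    snp_ids = np.array([f"snp{k}" for k in range(m)], dtype=object)
    return GenotypeMatrix(values=values, snp_ids=snp_ids, individual_ids=ind_ids)


def solve_prevalence_offset(linear_predictors: np.ndarray, target: float) -> float:
    """Intercept c with mean_i sigma(eta_i + c) = target, by bisection.

    The mean is strictly increasing in c, so the root exists and is unique.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    eta = np.asarray(linear_predictors, dtype=float)

    def mean_prev(c: float) -> float:
        return float(expit(eta + c).mean())

    lo, hi = -1.0, 1.0
    while mean_prev(lo) > target:
        lo *= 2.0
    while mean_prev(hi) < target:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_prev(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    c = 0.5 * (lo + hi)
    return c


def _random_effect(K: np.ndarray, variance: float, rng: np.random.Generator) -> np.ndarray:
    if variance == 0.0:
        return np.zeros(K.shape[0])
    # jitter keeps the Cholesky well-posed for near-singular kinship
    n = K.shape[0]
    for eps in (0.0, 1e-6, 1e-4):
        try:
            L = np.linalg.cholesky(K + eps * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise ValueError("similarity matrix is not positive semidefinite")
    return np.sqrt(variance) * (L @ rng.standard_normal(n))


def simulate_phenotypes_glmm(
    geno_snp: np.ndarray,
    X: CovariateMatrix | None,
    K: SimilarityMatrix | np.ndarray,
    cfg: GlmmConfig,
    *,
    rng: np.random.Generator | None = None,
    chol: np.ndarray | None = None,
) -> PhenotypeVector:
    """Sample binary labels from the mixed model; seeded and reproducible.

    ``chol`` may carry a precomputed Cholesky factor of K (+jitter) so
    benchmark loops pay the factorization once.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    Kv = K.values if isinstance(K, SimilarityMatrix) else np.asarray(K, dtype=float)
    n = Kv.shape[0]
    eta = np.zeros(n)
    if geno_snp is not None and cfg.snp_weight != 0.0:
        eta = eta + cfg.snp_weight * np.asarray(geno_snp, dtype=float)
    if X is not None and cfg.covariate_weights is not None:
        eta = eta + X.values @ np.asarray(cfg.covariate_weights, dtype=float)
    if cfg.variance > 0.0:
        if chol is not None:
            eta = eta + np.sqrt(cfg.variance) * (chol @ rng.standard_normal(n))
        else:
            eta = eta + _random_effect(Kv, cfg.variance, rng)
    c = solve_prevalence_offset(eta, cfg.target_prevalence)
    labels = (rng.random(n) < expit(eta + c)).astype(np.int8)
    ids = K.individual_ids if isinstance(K, SimilarityMatrix) else None
    return PhenotypeVector(labels=labels, individual_ids=ids)


def cholesky_with_jitter(K: np.ndarray) -> np.ndarray:
    n = K.shape[0]
    for eps in (0.0, 1e-6, 1e-4):
        try:
            return np.linalg.cholesky(K + eps * np.eye(n))
        except np.linalg.LinAlgError:
            continue
    raise ValueError("similarity matrix is not positive semidefinite")


def build_benchmark(
    cfg_pop: PopulationConfig,
    beta_grid: tuple[float, ...] = (0.0, 0.1, 0.2, 0.5),
    reps: int = 50,
    *,
    glmm: GlmmConfig | None = None,
) -> list[SyntheticDataset]:
    """Per-SNP phenotype replicates over a grid of true SNP weights.

    One structured genotype panel and its IBS matrix are shared by all
    datasets.  For replicate r of weight beta, SNP r (standardized) is the
    causal/tested marker: a fresh random effect and labels are drawn with
    that SNP's weight set to beta.  The zero entry of the grid supplies the
    null SNPs that anchor false-positive rates, so it is required.
    """
    if 0.0 not in beta_grid:
        raise ValueError("beta_grid must contain 0 (null SNPs calibrate FP rates)")
    if reps > cfg_pop.n_snps:
        raise ValueError("reps may not exceed the number of SNPs in the panel")
    base = glmm or GlmmConfig()
    geno = simulate_genotypes(cfg_pop)
    sim = compute_ibs(geno)
    K = standardized_kinship(sim)
    chol = cholesky_with_jitter(K) if base.variance > 0 else None
    rng = np.random.default_rng(np.random.SeedSequence([cfg_pop.seed, 2**20 + base.seed]))

    out: list[SyntheticDataset] = []
    for beta in beta_grid:
        for r in range(reps):
            snp_id = str(geno.snp_ids[r])
            col = standardize_genotype_column(
                geno.values[:, r].astype(float), geno.missing_mask[:, r]
            )
            cfg = replace(base, snp_weight=beta)
            y = simulate_phenotypes_glmm(col, None, K, cfg, rng=rng, chol=chol)
            y = PhenotypeVector(labels=y.labels, individual_ids=geno.individual_ids)
            out.append(
                SyntheticDataset(
                    genotypes=geno,
                    covariates=None,
                    phenotypes=y,
                    similarity=sim,
                    truth_beta={snp_id: beta},
                    tested_snp=snp_id,
                )
            )
    return out
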