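"""Identity-by-state similarities and covariate preparation.

The IBS similarity between two individuals is the fraction of SNP-marker
alleles they share across the panel: at one locus with minor-allele counts
g_i and g_j, treating each genotype as an unordered allele pair, the shared
fraction is (2 - |g_i - g_j|) / 2.  Averaging over loci that are non-missing
in both individuals gives a symmetric matrix with entries in [0, 1] and unit
diagonal.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import CovariateMatrix, GenotypeMatrix, SimilarityMatrix

__all__ = [
    "compute_ibs",
    "center_couplings",
    "standardized_kinship",
    "subcritical_couplings",
    "standardize",
    "bin_ages",
    "filter_snps",
    "standardize_genotype_column",
]


def compute_ibs(geno: GenotypeMatrix) -> SimilarityMatrix:
    """Compute the pairwise IBS allele-sharing matrix from the full panel.

    Missing genotypes are handled pairwise-complete: each pair is averaged
    over the loci observed in both individuals.  A pair with no jointly
    observed locus raises, naming the pair.
    """
    g = geno.values.astype(float)
    obs = (~geno.missing_mask).astype(float)
    g = np.where(geno.missing_mask, 0.0, g)

    # 2 - |g_i - g_j| per locus, summed over jointly observed loci, via
    # one-hot expansion so everything is dense matrix products.
    onehot = [((g == v) & ~geno.missing_mask).astype(float) for v in (0.0, 1.0, 2.0)]
    n_joint = obs @ obs.T
    shared = np.zeros_like(n_joint)
    for a, ga in enumerate(onehot):
        for b, gb in enumerate(onehot):
            share = 2 - abs(a - b)
            if share:
                shared += share * (ga @ gb.T)

    bad = n_joint == 0
    np.fill_diagonal(bad, False)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            "no jointly observed loci for pair "
            f"({geno.individual_ids[i]}, {geno.individual_ids[j]})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = shared / (2.0 * n_joint)
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(values=values, individual_ids=geno.individual_ids)


def center_couplings(sim: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Turn a similarity matrix into coupling weights by Gower double
    centering (subtract row and column means, add back the grand mean).

    Raw IBS similarities sit on a large common baseline (unrelated humans
    already share most alleles) plus per-individual row effects (a highly
    heterozygous individual shares at least one allele with everyone).
    Summed over hundreds of neighbours, the baseline saturates the
    conditional probabilities and the row effects leak each individual's
    genotype make-up into every offset, biasing every SNP test.  Double
    centering removes both, leaving the relatedness structure in excess of
    the sample average — the standard similarity-to-kernel transform.  The
    diagonal is zeroed (self-edges are excluded by definition).
    """
    a = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    c = a - row - row.T + a.mean()
    np.fill_diagonal(c, 0.0)
    return c


def standardized_kinship(sim: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Unit-mean-diagonal kinship kernel from a similarity matrix.

    The Gower-centered similarity rescaled so the mean diagonal entry is 1,
    making it directly usable as the covariance of a per-individual genetic
    random effect with variance sigma^2 (the covariance-matrix reading of
    the similarities used by mixed-model methods).
    """
    a = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    k = a - row - row.T + a.mean()
    d = np.mean(np.diag(k))
    if d <= 0:
        raise ValueError("degenerate similarity matrix: non-positive centered diagonal")
    return k / d


def subcritical_couplings(sim: SimilarityMatrix | np.ndarray, nu: float = 0.5) -> np.ndarray:
    """Centered couplings scaled below the order transition of the field.

    A fully connected binary random field with coupling matrix C develops a
    frozen (spontaneously ordered) phase once 2*lambda_max(C) exceeds 1;
    sampling and pseudo-likelihood asymptotics only behave in the unique-
    phase regime.  This returns the Gower-centered couplings scaled so
    2*lambda_max equals ``nu`` < 1 (default halfway to criticality); used
    when the random field itself is the generative model.
    """
    if not 0.0 < nu < 1.0:
        raise ValueError("nu must be in (0, 1)")
    c = center_couplings(sim)
    lam = float(np.linalg.eigvalsh(c)[-1])
    if lam <= 0:
        raise ValueError("centered couplings have no positive eigenvalue")
    return (nu / (2.0 * lam)) * c


def standardize(cov: CovariateMatrix) -> CovariateMatrix:
    """Column-wise z-scores using the population (divide-by-n) SD.

    Constant columns cannot be scaled; they are mapped to all-zeros and
    recorded in ``constant_columns`` with a warning.
    """
    x = cov.values
    if x.shape[0] < 2:
        raise ValueError("standardization needs at least 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    constant = sd <= 1e-12 * (1.0 + np.abs(mean))
    safe_sd = np.where(constant, 1.0, sd)
    z = (x - mean) / safe_sd
    z[:, constant] = 0.0
    const_names = tuple(str(nm) for nm in np.asarray(cov.names)[constant])
    if const_names:
        warnings.warn(f"constant covariate columns zeroed: {const_names}", stacklevel=2)
    return CovariateMatrix(
        values=z, names=cov.names, standardized=True, constant_columns=const_names
    )


def standardize_genotype_column(column: np.ndarray, missing: np.ndarray | None = None) -> np.ndarray:
    """Mean-impute missing entries then z-score one SNP column.

    Returns an all-zero column when the SNP is monomorphic (the caller flags
    it untestable).
    """
    x = np.asarray(column, dtype=float)
    if missing is not None and missing.any():
        if missing.all():
            return np.zeros_like(x)
        x = np.where(missing, x[~missing].mean(), x)
    sd = x.std()
    if sd <= 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def bin_ages(ages: np.ndarray, edges: tuple[float, float, float, float]) -> CovariateMatrix:
    """One-hot encode ages into five ranges split at four cut points.

    Bins are half-open [lo, hi): an age equal to a cut point lands in the
    upper bin.  Ages below the first bin start (taken as 0) or non-finite
    ages are rejected.
    """
    ages = np.asarray(ages, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if edges.size != 4 or not (np.diff(edges) > 0).all():
        raise ValueError("need 4 strictly increasing age cut points")
    if not np.isfinite(ages).all():
        raise ValueError("non-finite age values")
    if (ages < 0).any():
        raise ValueError("negative age values")
    idx = np.searchsorted(edges, ages, side="right")
    onehot = np.zeros((ages.size, 5))
    onehot[np.arange(ages.size), idx] = 1.0
    lo = ["0"] + [f"{e:g}" for e in edges]
    hi = [f"{e:g}" for e in edges] + ["inf"]
    names = [f"age[{a},{b})" for a, b in zip(lo, hi)]
    return CovariateMatrix(values=onehot, names=np.array(names, dtype=object))


def minor_allele_frequency(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP frequency of the less frequent allele among observed calls."""
    g = np.where(geno.missing_mask, np.nan, geno.values.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(g, axis=0) / 2.0
    freq = np.nan_to_num(freq, nan=0.0)
    return np.minimum(freq, 1.0 - freq)


def filter_snps(
    geno: GenotypeMatrix, maf_min: float = 0.01, missing_max: float = 1.0
) -> GenotypeMatrix:
    """Keep SNPs with MAF >= maf_min and missing fraction <= missing_max."""
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= missing_max <= 1.0:
        raise ValueError("missing_max must be in [0, 1]")
    maf = minor_allele_frequency(geno)
    miss = geno.missing_mask.mean(axis=0)
    keep = (maf >= maf_min) & (miss <= missing_max)
    if not keep.any():
        raise ValueError("all SNPs removed by filters")
    return GenotypeMatrix(
        values=geno.values[:, keep],
        missing_mask=geno.missing_mask[:, keep],
        snp_ids=geno.snp_ids[keep],
        individual_ids=geno.individual_ids,
    )
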