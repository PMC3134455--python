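"""Lightweight containers shared across the package.

Individuals are keyed by string id everywhere; all joins between genotypes,
phenotypes and covariates are id-based, never positional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _as_ids(ids, n: int, prefix: str) -> np.ndarray:
    if ids is None:
        return np.array([f"{prefix}{k}" for k in range(n)], dtype=object)
    ids = np.asarray(ids, dtype=object)
    if ids.shape != (n,):
        raise ValueError(f"expected {n} ids, got shape {ids.shape}")
    if len(set(ids)) != n:
        raise ValueError("ids must be unique")
    return ids


@dataclass
class GenotypeMatrix:
    """Minor-allele counts for n individuals x m SNPs.

    ``values`` holds entries in {0, 1, 2}; positions flagged in
    ``missing_mask`` are ignored (their stored value is arbitrary).
    """

    values: np.ndarray
    missing_mask: np.ndarray | None = None
    snp_ids: np.ndarray | None = None
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 individuals and 1 SNP")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, m), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (n, m):
                raise ValueError("missing_mask shape does not match values")
        observed = self.values[~self.missing_mask]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            raise ValueError("non-missing genotypes must be 0, 1 or 2")
        self.snp_ids = _as_ids(self.snp_ids, m, "snp")
        self.individual_ids = _as_ids(self.individual_ids, n, "ind")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityMatrix:
    """Symmetric n x n pairwise genetic similarities in [0, 1].

    Off-diagonal entries weight the pairwise phenotype interactions of the
    random field; the diagonal is 1 by convention but self-edges never enter
    any model sum. The same matrix doubles as the covariance kernel K of the
    mixed-model phenotype simulator.
    """

    values: np.ndarray
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        self.individual_ids = _as_ids(self.individual_ids, n, "ind")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]


@dataclass
class CovariateMatrix:
    """Real n x p covariate design with column names."""

    values: np.ndarray
    names: np.ndarray | None = None
    standardized: bool = False
    constant_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        p = self.values.shape[1]
        self.names = _as_ids(self.names, p, "cov")


@dataclass
class PhenotypeVector:
    """Binary case/control labels with the +/-1 spin view used by the model."""

    labels: np.ndarray
    individual_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("phenotype must be a vector")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("phenotype labels must be 0/1")
        self.labels = self.labels.astype(np.int8)
        self.individual_ids = _as_ids(self.individual_ids, self.labels.size, "ind")

    @property
    def spins(self) -> np.ndarray:
        """Spin encoding s = 2y - 1 in {-1, +1}."""
        return (2 * self.labels.astype(int) - 1).astype(float)
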