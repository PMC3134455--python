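"""Readers and writers for the text formats the tool exchanges.

Genotypes come in as PLINK text (.ped with a companion .map) or as a TSV
matrix of minor-allele counts; phenotypes and covariates as TSV tables with
an id column.  All joins between files are id-based.  Malformed input is
rejected with the offending line or id named, never silently coerced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CovariateMatrix, GenotypeMatrix, PhenotypeVector, SimilarityMatrix
from .scan import ScanResult

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "read_covariates",
    "read_similarity",
    "write_similarity",
    "write_results",
    "write_report",
    "write_genotypes_tsv",
    "RunConfig",
]


@dataclass
class RunConfig:
    """Serializable record of one run's inputs and settings."""

    geno: str = ""
    pheno: str = ""
    covar: str = ""
    similarity: str = ""
    maf_min: float = 0.0
    missing_max: float = 1.0
    coupling: str = "centered"
    coupling_scale: str = "prefit"
    optimizer: str = "newton"
    eta: float = 0.01
    tol: float = 1e-8
    max_iter: int = 500
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _read_ped(path: Path) -> GenotypeMatrix:
    map_path = path.with_suffix(".map")
    if not map_path.exists():
        raise FileNotFoundError(f"companion map file not found: {map_path}")
    snp_ids = []
    for lineno, line in enumerate(map_path.read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 2:
            raise ValueError(f"{map_path}:{lineno}: expected >= 2 columns")
        snp_ids.append(parts[1])
    m = len(snp_ids)

    ids, allele_rows = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6 + 2 * m:
            raise ValueError(
                f"{path}:{lineno}: expected {6 + 2 * m} fields "
                f"(6 + 2 alleles x {m} SNPs), got {len(parts)}"
            )
        ids.append(parts[1])
        allele_rows.append(parts[6:])
    if not ids:
        raise ValueError(f"{path}: no individuals")
    alleles = np.array(allele_rows, dtype=object).reshape(len(ids), m, 2)

    n = len(ids)
    values = np.zeros((n, m), dtype=np.int8)
    missing = np.zeros((n, m), dtype=bool)
    for k in range(m):
        a = alleles[:, k, :]
        miss = (a == "0").any(axis=1)
        obs = a[~miss].ravel()
        symbols = sorted(set(obs))
        if len(symbols) > 2:
            raise ValueError(f"{path}: SNP {snp_ids[k]} has >2 alleles: {symbols}")
        bad = set(obs) - set("ACGT12")
        if bad:
            raise ValueError(f"{path}: SNP {snp_ids[k]}: unknown allele symbols {sorted(bad)}")
        if len(symbols) == 0:
            missing[:, k] = True
            continue
        # minor allele: less frequent in sample; ties broken lexicographically
        counts = {s: int((obs == s).sum()) for s in symbols}
        minor = min(symbols, key=lambda s: (counts[s], s))
        values[:, k] = (a == minor).sum(axis=1)
        missing[:, k] = miss
    return GenotypeMatrix(
        values=values, missing_mask=missing,
        snp_ids=np.array(snp_ids, dtype=object),
        individual_ids=np.array(ids, dtype=object),
    )


def _read_geno_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus at least one SNP column")
    ids = df.iloc[:, 0].astype(str).to_numpy(dtype=object)
    snp_ids = np.array(df.columns[1:], dtype=object)
    raw = df.iloc[:, 1:].to_numpy()
    vals = pd.to_numeric(pd.DataFrame(raw).stack(), errors="coerce").unstack().to_numpy()
    missing = ~np.isfinite(vals)
    vals = np.where(missing, 0, vals)
    if not np.isin(vals[~missing], (0, 1, 2)).all():
        bad = sorted(set(np.asarray(vals[~missing]).ravel()) - {0, 1, 2})
        raise ValueError(f"{path}: genotype values must be 0/1/2; found {bad[:5]}")
    return GenotypeMatrix(
        values=vals.astype(np.int8), missing_mask=missing,
        snp_ids=snp_ids, individual_ids=ids,
    )


def read_genotypes(path: str | Path, dialect: str = "auto") -> GenotypeMatrix:
    """Read genotypes as minor-allele counts from .ped/.map or TSV."""
    path = Path(path)
    if dialect == "auto":
        dialect = "ped" if path.suffix == ".ped" else "tsv"
    if dialect == "ped":
        return _read_ped(path)
    if dialect == "tsv":
        return _read_geno_tsv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _aligned_table(path: Path, geno: GenotypeMatrix) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    want = [str(i) for i in geno.individual_ids]
    missing = [i for i in want if i not in df.index]
    if missing:
        raise ValueError(f"{path}: ids present in genotypes but not here: {missing[:10]}")
    return df.loc[want]


def read_phenotypes(path: str | Path, geno: GenotypeMatrix, column: str | None = None) -> PhenotypeVector:
    """Binary phenotype aligned to the genotype individuals.

    Accepts 0/1 coding or the PLINK 1/2 case-control convention (remapped
    to 0/1).  Any other value is an error naming the offending ids.
    """
    df = _aligned_table(Path(path), geno)
    col = df[column] if column else df.iloc[:, 0]
    vals = pd.to_numeric(col, errors="coerce")
    if set(vals.dropna().unique()) <= {1.0, 2.0} and 2.0 in set(vals.dropna().unique()):
        vals = vals - 1.0  # PLINK case/control 1/2 -> 0/1
    bad = vals.index[~vals.isin([0.0, 1.0])].tolist()
    if bad:
        raise ValueError(f"{path}: non-binary phenotype for ids {bad[:10]}")
    return PhenotypeVector(
        labels=vals.to_numpy().astype(np.int8), individual_ids=geno.individual_ids
    )


def read_covariates(path: str | Path, geno: GenotypeMatrix) -> CovariateMatrix:
    df = _aligned_table(Path(path), geno)
    vals = df.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        bad = vals.columns[vals.isna().any()].tolist()
        raise ValueError(f"{path}: non-numeric covariate entries in columns {bad}")
    return CovariateMatrix(values=vals.to_numpy(float), names=np.array(df.columns, dtype=object))


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.individual_ids, columns=sim.individual_ids)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="id")


def read_similarity(path: str | Path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column ids differ")
    return SimilarityMatrix(
        values=df.to_numpy(float),
        individual_ids=np.array(df.columns, dtype=object),
    )


def write_genotypes_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    vals = geno.values.astype(object)
    vals[geno.missing_mask] = ""
    df = pd.DataFrame(vals, index=geno.individual_ids, columns=geno.snp_ids)
    df.to_csv(path, sep="\t", index_label="id")


def write_results(scan: ScanResult, path: str | Path, config: RunConfig | None = None) -> None:
    """Scan table as TSV; config and settings in '#' comment header lines.

    Untestable SNPs keep their row with empty statistic fields.  P-values
    carry at least six significant digits.
    """
    path = Path(path)
    lines = [f"# crfgwas scan: {json.dumps(scan.metadata, default=str)}"]
    if config is not None:
        lines.append(f"# config: {config.to_json()}")
    cols = ["snp_id", "beta", "se", "chi2", "p", "converged"]
    lines.append("\t".join(cols))
    for _, row in scan.table.iterrows():
        if row.get("testable", True) and np.isfinite(row["p"]):
            vals = [
                str(row["snp_id"]),
                f"{row['beta']:.10g}", f"{row['se']:.10g}",
                f"{row['chi2']:.10g}", f"{row['p']:.6g}",
                str(bool(row["converged"])),
            ]
        else:
            vals = [str(row["snp_id"]), "", "", "", "", str(bool(row["converged"]))]
        lines.append("\t".join(vals))
    path.write_text("\n".join(lines) + "\n")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float) + "\n")
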