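"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing dosage inside the float dosage matrix.
MISSING = np.nan

#: Closed vocabulary of gene classes; everything except protein_coding
#: counts as a putative regulator.
GENE_CLASSES = ("protein_coding", "TF", "miRNA", "lncRNA")
REGULATOR_CLASSES = ("TF", "miRNA", "lncRNA")


class ConfigError(ValueError):
    """Invalid configuration value."""


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input data violates a structural contract."""


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per SNP from a samples x SNPs dosage matrix.

    Missing dosages (NaN) are excluded per SNP. Returns the folded
    frequency min(p, 1-p) where p is the mean dosage / 2.
    """
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-dosage matrix with per-SNP metadata.

    Dosages count copies of the A1 allele (0, 1, 2; NaN = missing).
    ``snp_info`` is a DataFrame indexed by SNP id with columns
    ``chrom`` (string label), ``pos`` (1-based int), ``a1``, ``a2``,
    ``maf``.
    """

    dosages: np.ndarray
    snp_info: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosage matrix must be 2-D (samples x SNPs)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.snp_info) != m:
            raise ValidationError(
                f"{len(self.snp_info)} SNP records for {m} dosage columns"
            )
        if "maf" not in self.snp_info.columns:
            self.snp_info = self.snp_info.assign(maf=compute_maf(self.dosages))

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_info.index)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        """New matrix restricted to ``snp_ids`` (original column order kept)."""
        wanted = set(snp_ids)
        mask = np.fromiter(
            (s in wanted for s in self.snp_info.index), bool, self.n_snps
        )
        return GenotypeMatrix(
            self.dosages[:, mask], self.snp_info.loc[mask].copy(), list(self.sample_ids)
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        ids = [self.sample_ids[i] for i in idx]
        sub = GenotypeMatrix(self.dosages[idx], self.snp_info.copy(), ids)
        sub.snp_info["maf"] = compute_maf(sub.dosages)
        return sub


@dataclass
class QcConfig:
    """SNP quality-control settings.

    ``maf_min`` excludes SNPs with MAF strictly below the threshold
    (a SNP at exactly the threshold is kept).
    """

    maf_min: float = 0.05
    drop_sex_chromosomes: bool = True
    drop_unmapped: bool = True
    sex_chromosomes: tuple[str, ...] = ("X", "Y", "XY", "MT")
    unmapped_labels: tuple[str, ...] = ("0", "", "NA", "UN")

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ConfigError(f"maf_min must be in [0, 0.5], got {self.maf_min}")


@dataclass
class TraitTable:
    """Samples x traits phenotype table (NaN = missing record)."""

    sample_ids: list[str]
    trait_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.trait_names)):
            raise ValidationError("trait value shape does not match ids/names")
        if len(self.trait_names) < 2:
            raise ValidationError(
                "a trait table needs >= 2 traits (key trait plus at least one other)"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in trait table")

    def trait(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.trait_names
        )


@dataclass
class GeneAnnotation:
    """Gene intervals with class labels.

    ``genes`` is a DataFrame indexed by gene id with columns ``chrom``,
    ``start``, ``end`` (1-based inclusive), ``strand``, ``gene_class``.
    """

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "strand", "gene_class"}
        missing = need - set(self.genes.columns)
        if missing:
            raise ValidationError(f"annotation missing columns: {sorted(missing)}")
        if self.genes.index.duplicated().any():
            dupes = self.genes.index[self.genes.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        bad = self.genes[self.genes["start"] > self.genes["end"]]
        if len(bad):
            raise ValidationError(
                f"gene interval start > end for: {bad.index.tolist()[:5]}"
            )
        unknown = set(self.genes["gene_class"]) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene class token(s): {sorted(unknown)}")
        self.genes = self.genes.sort_values(["chrom", "start"], kind="stable")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes.index)

    def gene_class(self, gene_id: str) -> str:
        return str(self.genes.loc[gene_id, "gene_class"])


@dataclass
class GwasResult:
    """Per (SNP, trait) mixed-model association statistics.

    ``table`` has one row per (trait, SNP) with columns ``trait``,
    ``snp``, ``chrom``, ``pos``, ``effect``, ``se``, ``z``, ``p``, ``n``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"trait", "snp", "effect", "se", "z", "p", "n"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValidationError(f"GWAS table missing columns: {sorted(missing)}")

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.table["trait"]))

    def pivot(self, value: str) -> pd.DataFrame:
        """SNP x trait matrix of one statistic (NaN where missing)."""
        return self.table.pivot_table(
            index="snp", columns="trait", values=value, sort=False
        )


@dataclass
class VarianceEstimate:
    """REML variance components for a GRM-structured mixed model."""

    sigma_u2: float
    sigma_e2: float
    h2: float
    se_sigma_u2: float
    se_sigma_e2: float
    se_h2: float
    loglik: float
    converged: bool
    n: int = 0
    m_snps: int = 0
    flat_likelihood: bool = False

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0 or self.sigma_e2 < 0:
            raise ValidationError("variance components must be non-negative")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValidationError(f"h2 out of [0,1]: {self.h2}")


@dataclass
class Grm:
    """Genomic relationship matrix (Yang et al. scaling)."""

    values: np.ndarray
    m_snps: int
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValidationError("GRM must be square")
        if len(self.sample_ids) != n:
            raise ValidationError("GRM sample ids do not match dimension")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("GRM contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class QcReport:
    """Per-filter SNP removal counts from :func:`awmnet.data_io.qc_filter`."""

    n_input: int
    n_removed_maf: int = 0
    n_removed_sex: int = 0
    n_removed_unmapped: int = 0
    n_retained: int = 0
    removed: dict = field(default_factory=dict)
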