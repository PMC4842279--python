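"""GREML variance partitioning for SNP subsets and the random-subset null.

For a named SNP subset (e.g. the AWM SNPs, or all SNPs inside the genes
common to every breed) a GRM is built from just those SNPs and the
proportion of phenotypic variance it captures is estimated by REML.
Significance is judged against an empirical null: many equal-size
subsets drawn at random (without replacement) from the full post-QC
panel, each fitted the same way; the empirical p-value uses the
add-one permutation convention p = (1 + #{null >= observed}) / (n + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from awmnet.datatypes import ConfigError, GenotypeMatrix, ValidationError, VarianceEstimate
from awmnet.gwas import compute_grm, reml_null


@dataclass
class SubsetVarianceReport:
    """Observed subset h2 plus its random-subset null distribution."""

    subset_name: str
    n_snps: int
    estimate: VarianceEstimate
    null_h2: np.ndarray
    n_reps: int
    empirical_p: float
    seed: int | None = None


def subset_variance(
    y: np.ndarray,
    g: GenotypeMatrix,
    snp_ids,
    compute_se: bool = True,
) -> VarianceEstimate:
    """Proportion of phenotypic variance explained by a SNP subset."""
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ConfigError("empty SNP subset")
    have = set(g.snp_info.index)
    missing = [s for s in snp_ids if s not in have]
    if missing:
        raise ValidationError(f"subset SNPs absent from panel: {missing[:5]}")
    if len(snp_ids) < 10:
        warnings.warn(
            f"subset of {len(snp_ids)} SNPs: variance estimates will be unstable"
        )
    sub = g.subset_snps(snp_ids)
    return reml_null(y, compute_grm(sub), compute_se=compute_se)


def random_subset_null(
    y: np.ndarray,
    g: GenotypeMatrix,
    size: int,
    n_reps: int = 200,
    seed: int | None = None,
    observed: VarianceEstimate | None = None,
    subset_name: str = "random",
) -> SubsetVarianceReport:
    """Null distribution of h2 for random SNP subsets of a given size.

    Subsets are sampled without replacement from the panel; each
    replicate builds its own GRM and REML fit. If ``observed`` is given
    its empirical p-value against the null is reported.
    """
    if n_reps < 1:
        raise ConfigError("n_reps must be >= 1")
    if size > g.n_snps:
        raise ConfigError(f"subset size {size} exceeds panel size {g.n_snps}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(g.snp_info.index)
    null = np.empty(n_reps)
    for rep in range(n_reps):
        pick = rng.choice(ids, size=size, replace=False)
        est = subset_variance(y, g, pick, compute_se=False)
        null[rep] = est.h2
    p = np.nan
    if observed is not None:
        p = empirical_p(observed.h2, null)
    return SubsetVarianceReport(
        subset_name=subset_name,
        n_snps=size,
        estimate=observed,
        null_h2=null,
        n_reps=n_reps,
        empirical_p=float(p),
        seed=seed,
    )


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Add-one permutation p-value: (1 + #{null >= observed}) / (n + 1)."""
    null = np.asarray(null)
    return float((1 + int((null >= observed).sum())) / (len(null) + 1))


def variance_report(
    datasets: dict[str, tuple[np.ndarray, GenotypeMatrix]],
    awm_snps: dict[str, list[str]],
    common_gene_snps: dict[str, list[str]],
    n_reps: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-breed variance partition: AWM SNPs, common-gene SNPs, and the
    equal-size random-subset null (mean +/- SD and empirical p).

    ``datasets`` maps breed -> (key-trait phenotype, post-QC genotypes).
    Missing breeds in either SNP map produce a partial report with a
    warning rather than an error.
    """
    rows = []
    for i, (breed, (y, g)) in enumerate(datasets.items()):
        row: dict = {"breed": breed}
        if breed not in awm_snps or breed not in common_gene_snps:
            warnings.warn(f"breed {breed}: missing SNP subset(s), partial report")
        if breed in awm_snps and awm_snps[breed]:
            est = subset_variance(y, g, awm_snps[breed])
            row.update(
                awm_n_snps=len(awm_snps[breed]),
                awm_h2=est.h2,
                awm_se=est.se_h2,
            )
        if breed in common_gene_snps and common_gene_snps[breed]:
            snps = common_gene_snps[breed]
            est = subset_variance(y, g, snps)
            rep_seed = None if seed is None else seed + i
            rep = random_subset_null(
                y, g, size=len(snps), n_reps=n_reps, seed=rep_seed,
                observed=est, subset_name=f"{breed}_common_genes",
            )
            row.update(
                common_n_snps=len(snps),
                common_h2=est.h2,
                common_se=est.se_h2,
                random_h2_mean=float(rep.null_h2.mean()),
                random_h2_sd=float(rep.null_h2.std(ddof=1)) if n_reps > 1 else np.nan,
                empirical_p=rep.empirical_p,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("breed")
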