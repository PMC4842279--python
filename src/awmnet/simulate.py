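"""Synthetic multi-breed genotype/phenotype/annotation generator.

The generator produces the statistical structure the downstream analysis
assumes: several breed cohorts whose allele frequencies diverge under a
Balding-Nichols model parameterized by FST, Hardy-Weinberg genotypes
(optionally with blockwise LD from latent haplotype copying), a gene map
with regulator class labels, and a panel of genetically correlated
traits driven by a causal architecture in which some causal genes are
shared across breeds and others are breed-specific. The key trait loads
on every causal gene, mirroring the premise that a key phenotype tags
pleiotropic genes. Phenotypes are produced already adjusted for
systematic environmental effects, so no fixed-effect structure beyond an
intercept is simulated.

Ground truth (causal genes/SNPs, true effects, realized heritabilities)
is returned alongside the data for parameter-recovery testing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from awmnet import data_io
from awmnet.datatypes import (
    ConfigError,
    GeneAnnotation,
    GenotypeMatrix,
    TraitTable,
    ValidationError,
    compute_maf,
)

_GENE_LEN = 20_000  # bp per gene body
_GENE_GAP = 30_000  # bp between consecutive gene bodies
_NEAR_WINDOW = 10_000  # bp flank counted as "near gene"
_LD_MUTATION = 0.02  # per-SNP flip probability in haplotype copying


def default_genetic_corr(n_traits: int, r_within: float = 0.6, r_between: float = 0.1,
                         block: int = 4) -> np.ndarray:
    """Block-structured trait correlation matrix (unit diagonal, PSD).

    Traits fall into consecutive blocks of size ``block`` with
    correlation ``r_within`` inside a block and ``r_between`` across
    blocks — a minimal stand-in for the clustered genetic-correlation
    structure of real multi-trait panels.
    """
    g = np.full((n_traits, n_traits), r_between)
    for s in range(0, n_traits, block):
        g[s : s + block, s : s + block] = r_within
    np.fill_diagonal(g, 1.0)
    w = np.linalg.eigvalsh(g)
    if w.min() < 1e-10:  # nudge onto the PSD cone
        g = g + (1e-8 - w.min()) * np.eye(n_traits)
        g = g / np.sqrt(np.outer(np.diag(g), np.diag(g)))
    return g


@dataclass
class SimConfig:
    """All knobs of the synthetic multi-breed dataset.

    Defaults give a desk-scale analogue of a three-breed beef-cattle
    study: 3 cohorts x 500 animals, 5,000 SNPs on 5 chromosomes,
    300 genes, 8 correlated traits with the first as key phenotype.
    """

    n_breeds: int = 3
    n_per_breed: int = 500
    n_snps: int = 5_000
    n_genes: int = 300
    n_chromosomes: int = 5
    fst: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    n_traits: int = 8
    key_trait_index: int = 0
    genetic_corr: np.ndarray | None = None
    h2: np.ndarray | float = 0.35
    n_causal_genes: int = 30
    shared_causal_fraction: float = 0.5
    regulator_fractions: tuple[float, float, float] = (0.08, 0.02, 0.02)
    ld_block_size: int = 1
    seed: int = 0
    # share of genetic variance carried by the causal-gene SNPs
    # (the remainder is an infinitesimal term over non-causal SNPs)
    causal_var_fraction: float = 0.8
    # deterministic SNP placement fractions (in gene body / within 10 kb)
    frac_snps_in_gene: float = 0.35
    frac_snps_near_gene: float = 0.25
    breed_names: list[str] | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fst) and 0.0 < self.fst < 1.0):
            raise ConfigError(f"fst must be in (0, 1), got {self.fst}")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"ancestral_maf_range must be within (0, 0.5]: {lo, hi}")
        if self.n_causal_genes > self.n_genes:
            raise ConfigError("n_causal_genes exceeds n_genes")
        if not 0.0 <= self.shared_causal_fraction <= 1.0:
            raise ConfigError("shared_causal_fraction must be in [0, 1]")
        if sum(self.regulator_fractions) > 1.0:
            raise ConfigError("regulator_fractions sum above 1")
        if not 0.0 < self.causal_var_fraction <= 1.0:
            raise ConfigError("causal_var_fraction must be in (0, 1]")
        if self.frac_snps_in_gene + self.frac_snps_near_gene > 1.0:
            raise ConfigError("SNP placement fractions sum above 1")
        self.h2 = np.broadcast_to(np.asarray(self.h2, float), (self.n_traits,)).copy()
        if np.any(self.h2 < 0) or np.any(self.h2 >= 1):
            raise ConfigError("h2 entries must lie in [0, 1)")
        if self.genetic_corr is None:
            self.genetic_corr = default_genetic_corr(self.n_traits)
        self.genetic_corr = np.asarray(self.genetic_corr, float)
        gc = self.genetic_corr
        if gc.shape != (self.n_traits, self.n_traits):
            raise ConfigError("genetic_corr shape must be n_traits x n_traits")
        if not np.allclose(gc, gc.T, atol=1e-10):
            raise ConfigError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(gc), 1.0, atol=1e-8):
            raise ConfigError("genetic_corr must have unit diagonal")
        if np.linalg.eigvalsh(gc).min() < -1e-8:
            raise ConfigError("genetic_corr must be positive semi-definite")
        if not 0 <= self.key_trait_index < self.n_traits:
            raise ConfigError("key_trait_index out of range")
        if self.breed_names is None:
            self.breed_names = [f"breed{i + 1}" for i in range(self.n_breeds)]

    @property
    def trait_names(self) -> list[str]:
        names = [f"trait{j + 1}" for j in range(self.n_traits)]
        names[self.key_trait_index] = "KEY"
        return names

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream per generation stage."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests."""

    causal_gene_ids: dict[str, list[str]]
    causal_snp_ids: dict[str, list[str]]
    effects: dict[str, pd.DataFrame]  # breed -> causal SNP x trait true effects
    genetic_values: dict[str, np.ndarray]  # breed -> n x traits true genetic value
    realized_h2: dict[str, np.ndarray]
    breed_freqs: pd.DataFrame  # breed x SNP allele frequencies
    shared_causal_genes: list[str]


@dataclass
class SimDataset:
    """A complete simulated multi-breed dataset."""

    config: SimConfig
    genotypes: dict[str, GenotypeMatrix]
    traits: dict[str, TraitTable]
    annotation: GeneAnnotation
    truth: SimTruth
    freqs: pd.DataFrame = field(repr=False, default=None)


def simulate_frequencies(config: SimConfig) -> pd.DataFrame:
    """Breed x SNP allele frequencies under the Balding-Nichols model.

    Ancestral frequencies are drawn uniformly from the configured MAF
    range and mirrored to either allele with equal probability; each
    breed's frequency is then Beta(p(1-F)/F, (1-p)(1-F)/F) around the
    ancestral p, clamped to [0.01, 0.99].
    """
    rng = config.rng(0)
    lo, hi = config.ancestral_maf_range
    p = rng.uniform(lo, hi, size=config.n_snps)
    flip = rng.random(config.n_snps) < 0.5
    p = np.where(flip, 1.0 - p, p)
    f = config.fst
    a, b = p * (1 - f) / f, (1 - p) * (1 - f) / f
    freqs = rng.beta(
        np.broadcast_to(a, (config.n_breeds, config.n_snps)),
        np.broadcast_to(b, (config.n_breeds, config.n_snps)),
    )
    freqs = np.clip(freqs, 0.01, 0.99)
    snp_ids = [f"snp{i + 1:05d}" for i in range(config.n_snps)]
    return pd.DataFrame(freqs, index=config.breed_names, columns=snp_ids)


def simulate_annotation(config: SimConfig) -> tuple[GeneAnnotation, pd.DataFrame]:
    """Gene map plus deterministic SNP placement.

    Genes tile each chromosome as disjoint 20-kb bodies separated by
    30-kb gaps. SNP counts per placement zone (in gene / within 10 kb /
    intergenic) follow the configured fractions exactly; positions are
    evenly spaced within each zone, so placement is reproducible
    allocation rather than sampling.

    Returns the annotation and a SNP table (id, chrom, pos, zone,
    nearest gene) whose row order matches the frequency columns.
    """
    rng = config.rng(1)
    genes_per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    genes_per_chrom[: config.n_genes % config.n_chromosomes] += 1

    gene_rows = []
    gid = 0
    classes = _assign_gene_classes(config, rng)
    for c in range(config.n_chromosomes):
        pos = _GENE_GAP  # leading gap so flanks never go below 1
        for _ in range(genes_per_chrom[c]):
            start, end = pos, pos + _GENE_LEN - 1
            gene_rows.append(
                (f"gene{gid + 1:04d}", str(c + 1), start, end, "+", classes[gid])
            )
            gid += 1
            pos = end + 1 + _GENE_GAP
    genes = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "start", "end", "strand", "gene_class"]
    ).set_index("gene")
    ann = GeneAnnotation(genes)

    n_in = round(config.frac_snps_in_gene * config.n_snps)
    n_near = round(config.frac_snps_near_gene * config.n_snps)
    n_far = config.n_snps - n_in - n_near

    snp_rows = []  # (chrom, pos, zone, gene)
    order = list(genes.index)
    for zone, count in (("in_gene", n_in), ("near_gene", n_near), ("intergenic", n_far)):
        per_gene = np.full(len(order), count // len(order))
        per_gene[: count % len(order)] += 1
        for g_i, gene in enumerate(order):
            k = per_gene[g_i]
            if k == 0:
                continue
            row = genes.loc[gene]
            if zone == "in_gene":
                lo_z, hi_z = int(row["start"]) + 1, int(row["end"]) - 1
            elif zone == "near_gene":
                # upstream flank, strictly within the 10-kb window
                lo_z, hi_z = int(row["start"]) - _NEAR_WINDOW, int(row["start"]) - 1
            else:
                # middle of the downstream gap: > 10 kb from both neighbors
                lo_z = int(row["end"]) + _NEAR_WINDOW + 1000
                hi_z = int(row["end"]) + _GENE_GAP - _NEAR_WINDOW - 1000
            offsets = np.linspace(lo_z, hi_z, k + 2)[1:-1]
            for p in offsets:
                snp_rows.append((str(row["chrom"]), int(p), zone, gene))

    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "zone", "gene"])
    snps = snps.sort_values(
        ["chrom", "pos"], key=lambda s: s.astype(int) if s.name != "zone" else s,
        kind="stable",
    ).reset_index(drop=True)
    # de-duplicate any position collisions deterministically
    snps["pos"] = _make_positions_unique(snps)
    snps.index = pd.Index([f"snp{i + 1:05d}" for i in range(len(snps))], name="snp")
    return ann, snps


def _assign_gene_classes(config: SimConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_genes
    tf, mirna, lnc = (round(f * n) for f in config.regulator_fractions)
    classes = (
        ["TF"] * tf + ["miRNA"] * mirna + ["lncRNA"] * lnc
        + ["protein_coding"] * (n - tf - mirna - lnc)
    )
    rng.shuffle(classes)
    return classes


def _make_positions_unique(snps: pd.DataFrame) -> np.ndarray:
    pos = snps["pos"].to_numpy().copy()
    for c in snps["chrom"].unique():
        m = (snps["chrom"] == c).to_numpy()
        p = pos[m]
        for i in range(1, len(p)):
            if p[i] <= p[i - 1]:
                p[i] = p[i - 1] + 1
        pos[m] = p
    return pos


def simulate_genotypes(
    freqs: pd.DataFrame, config: SimConfig, snp_table: pd.DataFrame | None = None
) -> dict[str, GenotypeMatrix]:
    """Per-breed dosage matrices under within-breed Hardy-Weinberg.

    With ``ld_block_size == 1`` dosages are independent Binomial(2, p).
    With larger blocks, the two haplotypes of an individual are copied
    from a single latent uniform per block and per haplotype, thresholded
    against each SNP's frequency and flipped with a small per-SNP
    mutation probability — producing positive LD within a block that
    decays with the mutation rate.
    """
    if snp_table is None:
        _, snp_table = simulate_annotation(config)
    if not ((freqs.values > 0).all() and (freqs.values < 1).all()):
        raise ConfigError("allele frequencies must lie strictly in (0, 1)")
    rng = config.rng(2)
    out: dict[str, GenotypeMatrix] = {}
    n, m = config.n_per_breed, config.n_snps
    for b_i, breed in enumerate(freqs.index):
        p = freqs.loc[breed].to_numpy()
        if config.ld_block_size <= 1:
            dos = rng.binomial(2, p, size=(n, m)).astype(float)
        else:
            dos = _ld_block_genotypes(p, n, config.ld_block_size, rng)
        info = pd.DataFrame(
            {
                "chrom": snp_table["chrom"].values,
                "pos": snp_table["pos"].values,
                "a1": "A",
                "a2": "B",
            },
            index=snp_table.index.copy(),
        )
        info["maf"] = compute_maf(dos)
        out[breed] = GenotypeMatrix(
            dos, info, [f"{breed}_ind{i + 1:04d}" for i in range(n)]
        )
    return out


def _ld_block_genotypes(
    p: np.ndarray, n: int, block: int, rng: np.random.Generator
) -> np.ndarray:
    m = len(p)
    n_blocks = (m + block - 1) // block
    dos = np.empty((n, m))
    for h in range(2):  # two haplotypes per individual
        u_block = rng.random((n, n_blocks))
        u = np.repeat(u_block, block, axis=1)[:, :m]
        hap = (u < p).astype(float)
        flip = rng.random((n, m)) < _LD_MUTATION
        hap = np.where(flip, 1.0 - hap, hap)
        if h == 0:
            dos = hap
        else:
            dos = dos + hap
    return dos


def simulate_phenotypes(
    genotypes: dict[str, GenotypeMatrix],
    annotation: GeneAnnotation,
    config: SimConfig,
    snp_table: pd.DataFrame | None = None,
) -> tuple[dict[str, TraitTable], SimTruth]:
    """Correlated phenotypes with a shared/breed-specific causal architecture.

    Causal genes are drawn among genes that physically contain SNPs; a
    ``shared_causal_fraction`` of them is common to all breeds and the
    rest are breed-specific. Each causal gene contributes through one
    causal SNP chosen inside its body — independently per breed, so
    shared genes typically act through different SNPs in different
    breeds. Per-trait causal effects are multivariate normal with the
    configured genetic correlation; an infinitesimal term over
    non-causal SNPs and Gaussian noise complete the phenotype, with
    empirical per-trait rescaling to hit the target heritabilities.
    """
    if snp_table is None:
        _, snp_table = simulate_annotation(config)
    rng = config.rng(3)
    in_gene = snp_table[snp_table["zone"] == "in_gene"]
    genes_with_snps = sorted(in_gene["gene"].unique())
    if config.n_causal_genes > len(genes_with_snps):
        raise ConfigError(
            f"n_causal_genes={config.n_causal_genes} exceeds the "
            f"{len(genes_with_snps)} genes containing SNPs"
        )

    n_shared = round(config.shared_causal_fraction * config.n_causal_genes)
    n_specific = config.n_causal_genes - n_shared
    pool = list(genes_with_snps)
    shared = sorted(rng.choice(pool, size=n_shared, replace=False))
    remaining = [g for g in pool if g not in set(shared)]

    causal_genes: dict[str, list[str]] = {}
    for breed in config.breed_names:
        if n_specific > len(remaining):
            raise ConfigError("not enough genes for breed-specific causal sets")
        own = sorted(rng.choice(remaining, size=n_specific, replace=False))
        remaining = [g for g in remaining if g not in set(own)]
        causal_genes[breed] = sorted(set(shared) | set(own))

    chol = np.linalg.cholesky(
        config.genetic_corr + 1e-10 * np.eye(config.n_traits)
    )
    traits: dict[str, TraitTable] = {}
    causal_snps: dict[str, list[str]] = {}
    effects: dict[str, pd.DataFrame] = {}
    gvalues: dict[str, np.ndarray] = {}
    realized: dict[str, np.ndarray] = {}

    for breed, g in genotypes.items():
        snp_ids = []
        for gene in causal_genes[breed]:
            inside = in_gene.index[in_gene["gene"] == gene]
            snp_ids.append(str(rng.choice(inside)))
        causal_snps[breed] = snp_ids

        # causal effects: rows = causal SNPs, columns = traits, with the
        # configured cross-trait correlation
        beta = rng.standard_normal((len(snp_ids), config.n_traits)) @ chol.T
        cols = [g.snp_info.index.get_loc(s) for s in snp_ids]
        x_causal = _standardize(g.dosages[:, cols])
        g_causal = x_causal @ beta

        non_causal = [i for i in range(g.n_snps) if i not in set(cols)]
        gamma = rng.standard_normal((len(non_causal), config.n_traits)) @ chol.T
        x_poly = _standardize(g.dosages[:, non_causal])
        g_poly = x_poly @ gamma

        n = g.n_samples
        y = np.empty((n, config.n_traits))
        g_total = np.empty_like(y)
        for t in range(config.n_traits):
            h2_t = config.h2[t]
            gc = _scale_to_var(g_causal[:, t], config.causal_var_fraction * h2_t)
            gp = _scale_to_var(g_poly[:, t], (1 - config.causal_var_fraction) * h2_t)
            gt = gc + gp
            e = rng.standard_normal(n)
            e = _scale_to_var(e, 1.0 - h2_t) if h2_t < 1 else np.zeros(n)
            if h2_t == 0 and e.std() == 0:
                raise ConfigError("h2=0 with zero noise variance is unidentifiable")
            y[:, t] = gt + e
            g_total[:, t] = gt

        var_y = y.var(axis=0, ddof=1)
        var_g = g_total.var(axis=0, ddof=1)
        realized[breed] = np.where(var_y > 0, var_g / var_y, 0.0)
        gvalues[breed] = g_total
        effects[breed] = pd.DataFrame(
            beta, index=pd.Index(snp_ids, name="snp"),
            columns=config.trait_names,
        )
        traits[breed] = TraitTable(
            sample_ids=list(g.sample_ids),
            trait_names=config.trait_names,
            values=y,
        )

    # sample A1-allele frequencies (unfolded), one row per breed
    freqs = pd.DataFrame(
        {b: np.nanmean(genotypes[b].dosages, axis=0) / 2.0 for b in genotypes},
    ).T
    freqs.columns = genotypes[config.breed_names[0]].snp_info.index
    truth = SimTruth(
        causal_gene_ids=causal_genes,
        causal_snp_ids=causal_snps,
        effects=effects,
        genetic_values=gvalues,
        realized_h2=realized,
        breed_freqs=freqs,
        shared_causal_genes=list(shared),
    )
    return traits, truth


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _scale_to_var(v: np.ndarray, target: float) -> np.ndarray:
    cur = v.var(ddof=1)
    if target <= 0 or cur == 0:
        return np.zeros_like(v)
    return (v - v.mean()) * np.sqrt(target / cur)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run every generation stage and assemble a complete dataset."""
    freqs = simulate_frequencies(config)
    ann, snp_table = simulate_annotation(config)
    freqs.columns = snp_table.index  # align ids to genome order
    genotypes = simulate_genotypes(freqs, config, snp_table)
    traits, truth = simulate_phenotypes(genotypes, ann, config, snp_table)
    truth.breed_freqs = freqs
    return SimDataset(
        config=config, genotypes=genotypes, traits=traits,
        annotation=ann, truth=truth, freqs=freqs,
    )


def write_dataset(dataset: SimDataset, out_dir: str | os.PathLike) -> None:
    """Persist a dataset: PLINK triplet + traits TSV per breed,
    annotation BED, and ground-truth tables under ``truth/``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for breed, g in dataset.genotypes.items():
        data_io.write_plink(g, out / breed)
        data_io.write_traits(dataset.traits[breed], out / f"{breed}.traits.tsv")
    data_io.write_annotation(dataset.annotation, out / "genes.bed")

    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    rows = []
    for breed in dataset.config.breed_names:
        for gene, snp in zip(
            dataset.truth.causal_gene_ids[breed],
            dataset.truth.causal_snp_ids[breed],
        ):
            rows.append((breed, gene, snp))
    pd.DataFrame(rows, columns=["breed", "causal_gene", "causal_snp"]).to_csv(
        tdir / "causal.tsv", sep="\t", index=False
    )
    for breed, eff in dataset.truth.effects.items():
        eff.to_csv(tdir / f"{breed}.effects.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame(
        dataset.truth.realized_h2, index=dataset.config.trait_names
    ).to_csv(tdir / "realized_h2.tsv", sep="\t", float_format="%.10g")
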