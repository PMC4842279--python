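"""Across-breed comparison of AWM outputs.

Quantifies how much of the candidate-gene signal is shared between
cohorts: exact set intersections of AWM genes and of their
representative SNPs at every order, the common-gene list, and overlap
percentages relative to the union of the compared sets. SNP overlap is
typically far smaller than gene overlap when causal mutations are
breed-specific but hit the same genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from awmnet.awm import Awm
from awmnet.datatypes import GeneAnnotation, GenotypeMatrix, ValidationError


@dataclass
class OverlapReport:
    """Gene/SNP set sizes and intersections across breeds."""

    set_sizes: dict[str, int]
    snp_set_sizes: dict[str, int]
    gene_intersections: dict[tuple[str, ...], int]
    snp_intersections: dict[tuple[str, ...], int]
    common_genes: list[str]
    common_snps: list[str]
    gene_overlap_pct: dict[tuple[str, ...], float]

    def to_json_dict(self) -> dict:
        key = lambda t: "&".join(t)
        return {
            "set_sizes": self.set_sizes,
            "snp_set_sizes": self.snp_set_sizes,
            "gene_intersections": {key(k): v for k, v in self.gene_intersections.items()},
            "snp_intersections": {key(k): v for k, v in self.snp_intersections.items()},
            "common_genes": self.common_genes,
            "common_snps": self.common_snps,
            "gene_overlap_pct": {key(k): v for k, v in self.gene_overlap_pct.items()},
        }


def _sets(awms: dict[str, Awm], attr: str) -> dict[str, set]:
    out = {}
    for breed, awm in awms.items():
        s = set(getattr(awm, attr))
        if not s:
            warnings.warn(f"breed {breed}: empty AWM ({attr})")
        out[breed] = s
    return out


def intersect_genes(awms: dict[str, Awm]) -> OverlapReport:
    """Gene and representative-SNP intersections at every order.

    Percentages are |k-way intersection| / |union of the compared
    sets| * 100; raw counts are reported alongside so any alternative
    denominator can be recomputed.
    """
    if len(awms) < 2:
        raise ValidationError("need >= 2 AWMs to intersect")
    gene_sets = _sets(awms, "gene_ids")
    snp_sets = _sets(awms, "snp_ids")
    breeds = sorted(awms)

    gene_int: dict[tuple[str, ...], int] = {}
    snp_int: dict[tuple[str, ...], int] = {}
    pct: dict[tuple[str, ...], float] = {}
    for k in range(2, len(breeds) + 1):
        for combo in combinations(breeds, k):
            gi = set.intersection(*(gene_sets[b] for b in combo))
            si = set.intersection(*(snp_sets[b] for b in combo))
            union = set.union(*(gene_sets[b] for b in combo))
            gene_int[combo] = len(gi)
            snp_int[combo] = len(si)
            pct[combo] = 100.0 * len(gi) / len(union) if union else 0.0

    all_breeds = tuple(breeds)
    common = sorted(set.intersection(*gene_sets.values()))
    common_snps = sorted(set.intersection(*snp_sets.values()))
    return OverlapReport(
        set_sizes={b: len(gene_sets[b]) for b in breeds},
        snp_set_sizes={b: len(snp_sets[b]) for b in breeds},
        gene_intersections=gene_int,
        snp_intersections=snp_int,
        common_genes=common,
        common_snps=common_snps,
        gene_overlap_pct=pct,
    )


def intersect_snps(awms: dict[str, Awm]) -> dict[tuple[str, ...], int]:
    """Representative-SNP intersection counts at every order."""
    return intersect_genes(awms).snp_intersections


def common_gene_snp_list(
    common_genes: list[str],
    panels: dict[str, GenotypeMatrix],
    ann: GeneAnnotation,
    window: int = 10_000,
) -> tuple[dict[str, list[str]], list[str]]:
    """Per-breed SNP ids inside the common genes (+/- window).

    Returns (breed -> SNP id list, genes absent from the annotation).
    Used to build the common-gene GRM for variance partitioning.
    """
    if not common_genes:
        warnings.warn("empty common-gene list: no SNPs selected")
        return {b: [] for b in panels}, []
    missing = [g for g in common_genes if g not in ann.genes.index]
    if missing:
        warnings.warn(f"genes absent from annotation, skipped: {missing[:5]}")
    keep = [g for g in common_genes if g in ann.genes.index]
    intervals = ann.genes.loc[keep, ["chrom", "start", "end"]]

    out: dict[str, list[str]] = {}
    for breed, g in panels.items():
        info = g.snp_info
        hit = pd.Series(False, index=info.index)
        for _, iv in intervals.iterrows():
            hit |= (
                (info["chrom"].astype(str) == str(iv["chrom"]))
                & (info["pos"] >= int(iv["start"]) - window)
                & (info["pos"] <= int(iv["end"]) + window)
            )
        out[breed] = list(info.index[hit])
    return out, missing
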