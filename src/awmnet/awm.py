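"""Association weight matrix construction and clustering.

The AWM is a genes x traits matrix of column-standardized SNP additive
effects. SNPs enter the matrix either because they associate with the
key phenotype (p <= alpha) or because they associate with at least Ap
other phenotypes at the same threshold, where Ap is the average number
of non-key phenotypes associated with the key-phenotype SNPs. Candidate
SNPs are then restricted to those inside a gene or within a window
(default 10 kb) of one, and each gene is reduced to a single
representative SNP — the one with the smallest key-trait p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from awmnet.datatypes import (
    ConfigError,
    GeneAnnotation,
    GwasResult,
    ValidationError,
)
from awmnet.gwas import zscore_effects


@dataclass
class AwmConfig:
    """Selection thresholds for AWM construction."""

    key_trait: str
    alpha: float = 0.01
    gene_window_bp: int = 10_000
    ap_override: int | None = None
    linkage: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if self.gene_window_bp < 0:
            raise ConfigError("gene_window_bp must be >= 0")


@dataclass
class Awm:
    """Gene x trait matrix of z-scored effects with row provenance.

    ``values`` is indexed by gene id with trait columns; ``rows`` holds
    per-gene provenance: representative SNP, selection reason
    (``key_trait`` or ``pleiotropy``), SNP-to-gene distance (0 inside
    the gene body), and the key-trait p-value of the representative SNP.
    """

    values: pd.DataFrame
    rows: pd.DataFrame
    key_trait: str
    ap: int
    config: AwmConfig = field(repr=False, default=None)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.rows["snp"])


def select_key_snps(res: GwasResult, cfg: AwmConfig) -> list[str]:
    """SNPs associated with the key trait at p <= alpha (inclusive)."""
    tab = res.table
    if cfg.key_trait not in set(tab["trait"]):
        raise ConfigError(f"key trait {cfg.key_trait!r} absent from GWAS results")
    key = tab[(tab["trait"] == cfg.key_trait) & (tab["p"] <= cfg.alpha)]
    snps = key["snp"].tolist()
    if not snps:
        import warnings

        warnings.warn(f"no SNP reached p <= {cfg.alpha} for {cfg.key_trait}")
    return snps


def _other_trait_counts(res: GwasResult, snps: list[str], cfg: AwmConfig) -> pd.Series:
    tab = res.table
    other = tab[(tab["trait"] != cfg.key_trait) & (tab["p"] <= cfg.alpha)]
    counts = other.groupby("snp", sort=False)["trait"].nunique()
    return counts.reindex(snps, fill_value=0) if snps is not None else counts


def compute_ap(res: GwasResult, key_snps: list[str], cfg: AwmConfig) -> int:
    """Average number of non-key phenotypes associated with the key SNPs.

    The mean count is rounded half-up to an integer and floored at 1.
    """
    if cfg.ap_override is not None:
        return max(int(cfg.ap_override), 1)
    if not key_snps:
        raise ValidationError(
            "no key-trait SNPs: Ap undefined, supply AwmConfig.ap_override"
        )
    counts = _other_trait_counts(res, key_snps, cfg)
    mean = float(counts.mean())
    ap = int(np.floor(mean + 0.5))  # round half-up
    return max(ap, 1)


def select_pleiotropic_snps(res: GwasResult, ap: int, cfg: AwmConfig) -> list[str]:
    """SNPs associated with >= ap non-key phenotypes at p <= alpha."""
    if ap < 1:
        raise ConfigError("ap must be >= 1")
    counts = _other_trait_counts(res, None, cfg)
    return counts.index[counts >= ap].tolist()


def map_snps_to_genes(
    snps: pd.DataFrame, ann: GeneAnnotation, cfg: AwmConfig
) -> pd.DataFrame:
    """Assign SNPs to genes within the gene body +/- window.

    A SNP maps to the gene with the smallest distance (0 inside the
    body), ties broken by smaller gene start. SNPs outside every window
    are dropped.

    ``snps``: DataFrame indexed by SNP id with columns chrom, pos.
    Returns a DataFrame indexed by SNP id with columns gene, distance.
    """
    w = cfg.gene_window_bp
    out_rows = []
    genes = ann.genes
    for chrom, gsub in genes.groupby("chrom", sort=False):
        ssub = snps[snps["chrom"].astype(str) == str(chrom)]
        if ssub.empty:
            continue
        starts = gsub["start"].to_numpy(int)
        ends = gsub["end"].to_numpy(int)
        ids = gsub.index.to_numpy()
        for snp, row in ssub.iterrows():
            pos = int(row["pos"])
            dist = np.where(
                pos < starts, starts - pos, np.where(pos > ends, pos - ends, 0)
            )
            ok = dist <= w
            if not ok.any():
                continue
            cand = np.nonzero(ok)[0]
            # smallest distance, then smallest gene start
            best = cand[np.lexsort((starts[cand], dist[cand]))[0]]
            out_rows.append((snp, ids[best], int(dist[best])))
    if not out_rows:
        return pd.DataFrame(columns=["gene", "distance"]).rename_axis("snp")
    return (
        pd.DataFrame(out_rows, columns=["snp", "gene", "distance"])
        .set_index("snp")
    )


def build_awm(
    res: GwasResult,
    ann: GeneAnnotation,
    cfg: AwmConfig,
    assignments: pd.DataFrame | None = None,
) -> Awm:
    """Full AWM construction from GWAS results.

    Pipeline: key-SNP selection -> Ap estimation -> pleiotropic-SNP
    union -> gene mapping -> one representative SNP per gene (smallest
    key-trait p; ties by distance then position) -> column z-scoring
    over the retained SNP set.
    """
    key_snps = select_key_snps(res, cfg)
    ap = compute_ap(res, key_snps, cfg) if key_snps else max(cfg.ap_override or 1, 1)
    pleio = select_pleiotropic_snps(res, ap, cfg)
    candidates = list(dict.fromkeys(list(key_snps) + [s for s in pleio]))

    tab = res.table
    key_tab = tab[tab["trait"] == cfg.key_trait].set_index("snp")
    if assignments is None:
        snp_pos = key_tab.loc[
            key_tab.index.intersection(candidates), ["chrom", "pos"]
        ]
        assignments = map_snps_to_genes(snp_pos, ann, cfg)
    cand_assigned = assignments.loc[assignments.index.intersection(candidates)]
    if cand_assigned.empty:
        raise ValidationError("no candidate SNP maps to any gene: empty AWM")

    key_set = set(key_snps)
    prov = cand_assigned.copy()
    prov["key_p"] = key_tab.loc[prov.index, "p"].to_numpy()
    prov["pos"] = key_tab.loc[prov.index, "pos"].to_numpy()
    prov["reason"] = [
        "key_trait" if s in key_set else "pleiotropy" for s in prov.index
    ]

    # representative SNP per gene: min key-trait p, ties by distance, position
    prov = prov.sort_values(["key_p", "distance", "pos"], kind="stable")
    rep = prov[~prov["gene"].duplicated()].copy()
    rep = rep.sort_values(["gene"], kind="stable")

    retained = GwasResult(tab[tab["snp"].isin(set(rep.index))].copy())
    z = zscore_effects(retained)
    z = z.loc[rep.index]  # SNP-indexed, one per gene
    # canonical column order: key trait first, others sorted
    other = sorted(c for c in z.columns if c != cfg.key_trait)
    values = z[[cfg.key_trait] + other].copy()
    values.index = pd.Index(rep["gene"], name="gene")

    rows = pd.DataFrame(
        {
            "snp": rep.index,
            "reason": rep["reason"].to_numpy(),
            "distance": rep["distance"].to_numpy(),
            "key_p": rep["key_p"].to_numpy(),
        },
        index=values.index,
    )
    if cfg.key_trait not in values.columns:
        raise ValidationError("key trait column missing from AWM")
    return Awm(values=values, rows=rows, key_trait=cfg.key_trait, ap=ap, config=cfg)


def cluster_awm(awm: Awm, linkage: str | None = None) -> dict:
    """Hierarchical clustering of AWM rows (genes) and columns (traits).

    Dissimilarity is 1 - Pearson correlation; linkage defaults to
    average. Returns leaf orders and scipy linkage matrices (merge
    heights included) for both axes.
    """
    link = linkage or (awm.config.linkage if awm.config else "average")
    m = awm.values.to_numpy()
    if m.shape[0] < 3 or m.shape[1] < 3:
        raise ValidationError("clustering needs >= 3 genes and >= 3 traits")

    out = {}
    for axis, labels in (("genes", awm.gene_ids), ("traits", list(awm.values.columns))):
        data = m if axis == "genes" else m.T
        corr = _safe_corr(data, labels)
        dist = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
        zmat = hierarchy.linkage(dist, method=link)
        order = hierarchy.leaves_list(zmat)
        out[axis] = {
            "order": [labels[i] for i in order],
            "linkage": zmat,
            "labels": labels,
        }
    return out


def _safe_corr(rows: np.ndarray, labels) -> np.ndarray:
    sd = rows.std(axis=1, ddof=1)
    bad = [labels[i] for i in np.nonzero(sd == 0)[0]]
    if bad:
        raise ValidationError(f"constant vector(s), correlation undefined: {bad[:5]}")
    c = np.corrcoef(rows)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def awm_trait_correlations(awm: Awm) -> pd.DataFrame:
    """Pearson correlations among AWM trait columns — the AWM analogue
    of the genetic correlation matrix."""
    cols = list(awm.values.columns)
    c = _safe_corr(awm.values.to_numpy().T, cols)
    return pd.DataFrame(c, index=cols, columns=cols)


def write_awm(awm: Awm, out_dir) -> None:
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    awm.values.to_csv(out / "awm.tsv", sep="\t", float_format="%.10g")
    awm.rows.to_csv(out / "awm_rows.tsv", sep="\t", float_format="%.10g")
    awm_trait_correlations(awm).to_csv(
        out / "trait_corr.tsv", sep="\t", float_format="%.10g"
    )
    (out / "awm_meta.json").write_text(
        json.dumps({"key_trait": awm.key_trait, "ap": awm.ap}, indent=2)
    )


def read_awm(out_dir) -> Awm:
    import json
    from pathlib import Path

    out = Path(out_dir)
    values = pd.read_csv(out / "awm.tsv", sep="\t", index_col=0)
    rows = pd.read_csv(out / "awm_rows.tsv", sep="\t", index_col=0)
    meta_path = out / "awm_meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        key_trait, ap = meta["key_trait"], int(meta["ap"])
    else:
        key_trait, ap = values.columns[0], 1
    return Awm(values=values, rows=rows, key_trait=key_trait, ap=ap)
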