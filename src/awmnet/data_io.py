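"""Readers/writers for genotypes, traits and annotation, plus SNP QC.

Genotypes travel as PLINK 1 binary triplets (``.bed``/``.bim``/``.fam``,
SNP-major v1.00 layout). Dosages are stored as the count of the bim A1
allele, so a ``.bed`` byte of ``00`` (homozygous A1) decodes to 2 and
``11`` (homozygous A2) to 0; ``01`` is the missing code and becomes NaN.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from awmnet.datatypes import (
    FormatError,
    GeneAnnotation,
    GenotypeMatrix,
    QcConfig,
    QcReport,
    TraitTable,
    ValidationError,
    compute_maf,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK genotype code -> A1-allele dosage (NaN = missing).
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triplet into a :class:`GenotypeMatrix`.

    Sample order follows the fam file; dosages count the bim A1 allele.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FormatError(f"missing PLINK file: {p}")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    sample_ids = fam.iloc[:, 1].tolist()
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    n, m = len(sample_ids), len(bim)

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes (not SNP-major bed v1.00)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: size {len(raw)} != expected {expected} "
            f"for {n} samples x {m} SNPs"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, low bits first within each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    dosages = _BED_DECODE[codes[:, :n]].T  # samples x SNPs

    snp_info = pd.DataFrame(
        {
            "chrom": bim["chrom"].values,
            "pos": bim["pos"].values.astype(int),
            "a1": bim["a1"].values,
            "a2": bim["a2"].values,
        },
        index=pd.Index(bim["snp"], name="snp"),
    )
    snp_info["maf"] = compute_maf(dosages)
    return GenotypeMatrix(dosages, snp_info, sample_ids)


def write_plink(g: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a :class:`GenotypeMatrix` as a PLINK bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.n_samples, g.n_snps

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in g.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for snp, row in g.snp_info.iterrows():
            fh.write(
                f"{row['chrom']}\t{snp}\t0\t{int(row['pos'])}\t"
                f"{row.get('a1', 'A')}\t{row.get('a2', 'B')}\n"
            )

    # dosage -> 2-bit code: 2->00, missing->01, 1->10, 0->11
    code = np.full(g.dosages.shape, 1, dtype=np.uint8)  # missing default
    code[g.dosages == 2] = 0
    code[g.dosages == 1] = 2
    code[g.dosages == 0] = 3
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = code.T
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def qc_filter(g: GenotypeMatrix, qc: QcConfig) -> tuple[GenotypeMatrix, QcReport]:
    """Apply SNP quality control: MAF, sex-chromosome and unmapped filters.

    A SNP is removed when its MAF is strictly below ``qc.maf_min``
    (equality keeps the SNP), when it maps to a sex chromosome (if
    flagged), or when its chromosome label marks it unmapped (if
    flagged). Filters are idempotent.
    """
    maf = compute_maf(g.dosages)
    chrom = g.snp_info["chrom"].astype(str).str.upper()

    bad_maf = maf < qc.maf_min
    bad_sex = (
        chrom.isin([c.upper() for c in qc.sex_chromosomes]).values
        if qc.drop_sex_chromosomes
        else np.zeros(g.n_snps, bool)
    )
    bad_unmapped = (
        chrom.isin([c.upper() for c in qc.unmapped_labels]).values
        if qc.drop_unmapped
        else np.zeros(g.n_snps, bool)
    )
    keep = ~(bad_maf | bad_sex | bad_unmapped)
    if not keep.any():
        raise ValidationError("QC removed every SNP: empty panel")

    report = QcReport(
        n_input=g.n_snps,
        n_removed_maf=int(bad_maf.sum()),
        n_removed_sex=int(bad_sex.sum()),
        n_removed_unmapped=int(bad_unmapped.sum()),
        n_retained=int(keep.sum()),
        removed={
            "maf": list(g.snp_info.index[bad_maf]),
            "sex": list(g.snp_info.index[bad_sex]),
            "unmapped": list(g.snp_info.index[bad_unmapped]),
        },
    )
    out = GenotypeMatrix(
        g.dosages[:, keep], g.snp_info.loc[keep].copy(), list(g.sample_ids)
    )
    out.snp_info["maf"] = maf[keep]
    return out, report


def read_traits(path: str | os.PathLike) -> TraitTable:
    """Read a TSV trait table: header row, sample id in the first column."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise ValidationError("trait table needs a sample-id column plus >= 2 traits")
    sample_ids = df.iloc[:, 0].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"duplicate sample ids in {path}")
    return TraitTable(
        sample_ids=sample_ids,
        trait_names=list(df.columns[1:]),
        values=df.iloc[:, 1:].to_numpy(float),
    )


def write_traits(traits: TraitTable, path: str | os.PathLike) -> None:
    if traits.values.size == 0:
        raise ValidationError("refusing to write an empty trait table")
    df = traits.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation(path: str | os.PathLike) -> GeneAnnotation:
    """Read gene annotation from BED6(+class) or GFF3 (gene features).

    BED half-open 0-based coordinates are converted to 1-based inclusive
    internally, matching bim positions for all distance computations.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or path.suffix.lower() in {".gff", ".gff3"}:
        return _read_gff3(path)
    return _read_bed(path)


def _read_bed(path: Path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: BED line with <4 columns: {line!r}")
            chrom, start0, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start0 >= end:
                raise ValidationError(
                    f"{path}: gene {name} has start >= end ({start0} >= {end})"
                )
            strand = parts[5] if len(parts) > 5 else "+"
            gene_class = parts[6] if len(parts) > 6 else "protein_coding"
            rows.append((name, chrom, start0 + 1, end, strand, gene_class))
    return _annotation_from_rows(rows)


def _read_gff3(path: Path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise FormatError(f"{path}: gene feature without ID attribute")
            gene_class = attrs.get("gene_class", attrs.get("biotype", "protein_coding"))
            start, end = int(parts[3]), int(parts[4])
            if start > end:
                raise ValidationError(f"{path}: gene {gene_id} start > end")
            rows.append((gene_id, parts[0], start, end, parts[6], gene_class))
    return _annotation_from_rows(rows)


def _annotation_from_rows(rows) -> GeneAnnotation:
    if not rows:
        raise ValidationError("annotation contains no gene records")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene ids in annotation")
    genes = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "strand", "gene_class"]
    ).set_index("gene")
    genes["chrom"] = genes["chrom"].astype(str)
    return GeneAnnotation(genes)


def write_annotation(ann: GeneAnnotation, path: str | os.PathLike) -> None:
    """Write annotation as BED6 + gene class in column 7."""
    with open(path, "w") as fh:
        for gene, row in ann.genes.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t"
                f"{gene}\t0\t{row['strand']}\t{row['gene_class']}\n"
            )
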