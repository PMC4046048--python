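"""Readers and writers for the external formats the pipeline touches.

VCF parsing goes through :mod:`cyvcf2`; writing uses a plain-text emitter
so phase separators and GQ fields are under explicit control. Tables
(EBV, pedigree, stage reports) are TSV with a header line.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    HaplotypeSet,
    MarkerPanel,
    SequenceVariantTable,
)


class FormatError(ValueError):
    """Raised when an input file violates a format precondition."""


# ---------------------------------------------------------------------------
# phased panel VCF


def read_phased_vcf(path: str | os.PathLike) -> tuple[MarkerPanel, HaplotypeSet]:
    """Read a phased biallelic VCF into a marker panel and haplotype set.

    The allele left of ``|`` becomes haplotype 1. Unphased or missing
    genotypes and multi-allelic records are errors: phasing is an upstream
    responsibility and dosage must be recomputable exactly.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    h1_cols, h2_cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {v.CHROM}:{v.POS} "
                f"(ALT={','.join(v.ALT)}); panel must be biallelic"
            )
        g = np.asarray(v.genotype.array())
        alleles = g[:, :2]
        phased = g[:, 2]
        if np.any(alleles < 0):
            raise FormatError(f"missing genotype at {v.CHROM}:{v.POS}")
        if not np.all(phased == 1):
            bad = samples[int(np.flatnonzero(phased != 1)[0])]
            raise FormatError(
                f"unphased genotype at {v.CHROM}:{v.POS} (sample {bad}); "
                "phased GT ('|') required"
            )
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, v.ALT[0]))
        h1_cols.append(alleles[:, 0].astype(np.int8))
        h2_cols.append(alleles[:, 1].astype(np.int8))
    if not rows:
        raise FormatError(f"no variant records in {path}")
    panel = MarkerPanel(
        pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    )
    hap1 = np.stack(h1_cols, axis=1)
    hap2 = np.stack(h2_cols, axis=1)
    return panel, HaplotypeSet(panel=panel, animal_ids=samples, hap1=hap1, hap2=hap2)


def write_phased_vcf(path: str | os.PathLike, haps: HaplotypeSet) -> None:
    """Write phased haplotypes as a VCF with ``|``-separated GT."""
    t = haps.panel.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(t["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(a) for a in haps.animal_ids)
            + "\n"
        )
        for k in range(haps.panel.n_markers):
            gts = "\t".join(
                f"{haps.hap1[i, k]}|{haps.hap2[i, k]}" for i in range(haps.n_animals)
            )
            fh.write(
                f"{t.chrom[k]}\t{t.pos[k]}\t{t.id[k]}\t{t.ref[k]}\t{t.alt[k]}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# sequence VCF with genotype quality


_GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def read_sequence_vcf(
    path: str | os.PathLike, sample_subset: list | None = None
) -> SequenceVariantTable:
    """Read sequence variants, collapsing genotypes to zygosity classes.

    Genotypes become HOM_REF / HET / HOM_ALT / MISSING; a GQ absent from a
    record is recorded as 0, so it can never pass a quality gate.
    """
    vcf = VCF(str(path))
    if sample_subset is not None:
        absent = sorted(set(map(str, sample_subset)) - set(vcf.samples))
        if absent:
            raise FormatError(f"samples not in VCF header: {', '.join(absent)}")
        vcf.set_samples([str(s) for s in sample_subset])
    samples = list(vcf.samples)
    rows, geno_rows, gq_rows = [], [], []
    for v in vcf:
        alt = ",".join(v.ALT) if v.ALT else "."
        vtype = (
            "SNP"
            if len(v.REF) == 1 and all(len(a) == 1 for a in v.ALT)
            else "indel"
        )
        g = np.asarray(v.genotype.array())[:, :2]
        zyg = np.full(len(samples), MISSING, dtype=np.int8)
        called = np.all(g >= 0, axis=1)
        hom = g[:, 0] == g[:, 1]
        zyg[called & hom & (g[:, 0] == 0)] = HOM_REF
        zyg[called & hom & (g[:, 0] > 0)] = HOM_ALT
        zyg[called & ~hom] = HET
        gq_field = v.format("GQ")
        if gq_field is None:
            gq = np.zeros(len(samples), dtype=np.int32)
        else:
            gq = np.asarray(gq_field).reshape(len(samples)).astype(np.int64)
            gq = np.where((gq < 0) | (gq > 10**6), 0, gq).astype(np.int32)
        rows.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}:{v.POS}", v.REF, alt, vtype))
        geno_rows.append(zyg)
        gq_rows.append(gq)
    if not rows:
        raise FormatError(f"no variant records in {path}")
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "vtype"]
    )
    return SequenceVariantTable(
        variants=variants,
        sample_ids=samples,
        geno=np.stack(geno_rows),
        gq=np.stack(gq_rows),
    )


def write_sequence_vcf(path: str | os.PathLike, table: SequenceVariantTable) -> None:
    """Write zygosity-class genotypes and GQ as an unphased VCF."""
    v = table.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in table.sample_ids)
            + "\n"
        )
        for k in range(table.n_variants):
            fields = "\t".join(
                f"{_GT_STRINGS[int(table.geno[k, i])]}:{int(table.gq[k, i])}"
                for i in range(len(table.sample_ids))
            )
            fh.write(
                f"{v.chrom[k]}\t{v.pos[k]}\t{v.id[k]}\t{v.ref[k]}\t{v.alt[k]}"
                f"\t.\tPASS\t.\tGT:GQ\t{fields}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables


def read_ebv_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read an EBV table (columns animal_id, ebv, pi, r2); validate r2."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    required = ["animal_id", "ebv", "pi", "r2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"EBV table lacks columns {missing}")
    bad = df.index[(df["r2"] < 0) | (df["r2"] >= 1)]
    if len(bad):
        row = int(bad[0])
        raise FormatError(
            f"reliability r2={df.loc[row, 'r2']} outside [0, 1) at row {row + 2} "
            f"(animal {df.loc[row, 'animal_id']})"
        )
    return df[required]


def write_ebv_table(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pedigree(path: str | os.PathLike) -> pd.DataFrame:
    """Pedigree TSV: animal_id, sire_id, dam_id ('0' = unknown parent)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"animal_id": str, "sire_id": str, "dam_id": str}
    )
    required = ["animal_id", "sire_id", "dam_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"pedigree lacks columns {missing}")
    return df[required].fillna("0")


def write_report(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write one pipeline stage's result table as TSV (deterministic)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_annotation_table(path: str | os.PathLike) -> pd.DataFrame:
    """Pre-computed annotation TSV keyed by chrom, pos, ref, alt."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "pos", "ref", "alt", "consequence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"annotation table lacks columns {missing}")
    return df[required]
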