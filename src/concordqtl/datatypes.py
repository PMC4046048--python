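"""Shared in-memory data model for the fine-mapping pipeline.

Genotypes at sequence variants are stored as zygosity codes rather than
allele pairs, because every downstream consumer (the concordance analysis
in particular) only distinguishes homozygous / heterozygous / missing.
Phased panel genotypes keep both haplotypes explicitly, since haplotype
effects are computed per chromosome copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# zygosity codes used throughout (SequenceVariantTable.geno)
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

STATUS_HOM = "hom"
STATUS_HET = "het"
STATUS_UNKNOWN = "unknown"


@dataclass
class MarkerPanel:
    """Ordered biallelic marker map (one row per marker).

    ``table`` has columns chrom, pos, id, ref, alt; positions are 1-based
    (VCF convention) and strictly increasing within a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "id", "ref", "alt"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker table lacks columns {missing}")
        self.table = self.table.reset_index(drop=True)
        if self.table["id"].duplicated().any():
            dup = self.table.loc[self.table["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_ranges(self) -> dict:
        """Map chromosome -> (start, stop) half-open global index range."""
        out = {}
        chrom = self.table["chrom"].to_numpy()
        for c in self.chroms:
            idx = np.flatnonzero(chrom == c)
            out[c] = (int(idx[0]), int(idx[-1]) + 1)
        return out

    def subset(self, indices) -> "MarkerPanel":
        return MarkerPanel(self.table.iloc[np.asarray(indices)].reset_index(drop=True))


@dataclass
class HaplotypeSet:
    """Phased haplotypes over a :class:`MarkerPanel`.

    ``hap1``/``hap2`` are (n_animals, n_markers) arrays of 0/1 alt-allele
    indicators; hap1 is the allele left of ``|`` in the VCF GT field.
    """

    panel: MarkerPanel
    animal_ids: list
    hap1: np.ndarray
    hap2: np.ndarray

    def __post_init__(self) -> None:
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        self.hap2 = np.asarray(self.hap2, dtype=np.int8)
        n, m = self.hap1.shape
        if self.hap2.shape != (n, m):
            raise ValueError("hap1/hap2 shape mismatch")
        if n != len(self.animal_ids):
            raise ValueError("animal_ids length does not match haplotype rows")
        if m != self.panel.n_markers:
            raise ValueError("haplotype length does not match marker panel")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    def dosages(self) -> np.ndarray:
        """Alt-allele dosage matrix (n_animals, n_markers), values 0/1/2."""
        return self.hap1.astype(np.int16) + self.hap2.astype(np.int16)

    def subset_markers(self, indices) -> "HaplotypeSet":
        idx = np.asarray(indices)
        return HaplotypeSet(
            panel=self.panel.subset(idx),
            animal_ids=list(self.animal_ids),
            hap1=self.hap1[:, idx],
            hap2=self.hap2[:, idx],
        )


@dataclass
class SequenceVariantTable:
    """Sequence variants (SNPs and indels) with per-sample zygosity and GQ.

    ``variants``: DataFrame chrom, pos, id, ref, alt, vtype ('SNP'/'indel'),
    sorted by position within chromosome. ``geno``: (n_variants, n_samples)
    int8 of HOM_REF/HET/HOM_ALT/MISSING. ``gq``: matching int array; a GQ
    absent from the VCF is recorded as 0 so it always fails quality gates.
    """

    variants: pd.DataFrame
    sample_ids: list
    geno: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=np.int32)
        nv = len(self.variants)
        ns = len(self.sample_ids)
        if self.geno.shape != (nv, ns) or self.gq.shape != (nv, ns):
            raise ValueError("geno/gq shape does not match variants x samples")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) < 0):
                raise ValueError(f"variants unsorted on chromosome {chrom}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset_region(self, chrom, start_bp: int, end_bp: int) -> "SequenceVariantTable":
        """Variants with chrom == chrom and start_bp <= pos <= end_bp."""
        v = self.variants
        mask = (v["chrom"] == chrom) & (v["pos"] >= start_bp) & (v["pos"] <= end_bp)
        idx = np.flatnonzero(mask.to_numpy())
        return SequenceVariantTable(
            variants=v.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            geno=self.geno[idx],
            gq=self.gq[idx],
        )


@dataclass
class DeregressedRecord:
    """One animal's deregressed pseudo-phenotype and its weight."""

    animal_id: str
    ebv: float
    pi: float
    r2: float
    h2: float
    y: float
    w: float


@dataclass
class PosteriorSummary:
    """Per-marker posterior summaries from a Bayes C chain.

    ``p`` is the posterior inclusion probability (fraction of retained
    samples with a nonzero effect); ``a_hat`` averages the sampled effect
    over all retained samples, counting 0 when the marker is excluded.
    """

    marker_ids: list
    p: np.ndarray
    a_hat: np.ndarray
    mu_mean: float
    sigma2_a_mean: float
    sigma2_e_mean: float
    sigma2_u_mean: float | None
    n_retained: int

    def to_frame(self, panel: MarkerPanel | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"marker_id": self.marker_ids, "p": self.p, "a_hat": self.a_hat}
        )
        if panel is not None:
            df.insert(1, "chrom", panel.table["chrom"].to_numpy())
            df.insert(2, "pos", panel.table["pos"].to_numpy())
        return df


@dataclass
class QTLRegion:
    """A contiguous marker interval selected as a QTL region.

    Marker indices are global (into the filtered panel), inclusive.
    ``subintervals`` maps sub-interval length L' -> (start_idx, end_idx,
    sum_p) for the contiguous block of L' markers maximising its summed
    inclusion probability inside the region.
    """

    chrom: object
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    sum_p: float
    rank: int
    subintervals: dict = field(default_factory=dict)

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx + 1

    def marker_indices(self, subinterval: int | None = None) -> np.ndarray:
        if subinterval is None:
            return np.arange(self.start_idx, self.end_idx + 1)
        s, e, _ = self.subintervals[subinterval]
        return np.arange(s, e + 1)
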