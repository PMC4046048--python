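"""Synthetic populations with a planted causative variant.

The generator emulates the study design the pipeline targets: a dense
panel of sequence variants carrying one causative site, a sparse
"50K-like" marker subset that deliberately excludes that site (so mapping
must work through linkage disequilibrium), per-animal EBVs with
heterogeneous reliabilities, and sequence genotypes perturbed by an error
model with genotype-quality scores that do *not* flag the errors.

LD is produced by a founder-copying mosaic. A small pool of founder
haplotypes is drawn once with distance-decaying allelic correlation (a
latent AR(1) Gaussian copula with per-step correlation
``founder_ld_rho`` thresholded at each site's allele frequency — the
ancestral LD). Each sample haplotype then walks the variant map left to
right, copying the current founder's allele with probability ``ld_rho``
and otherwise drawing a fresh allele from the site frequency and
re-picking the founder it tracks — the recombination/mutation analogue
that breaks blocks up. |D'| decays with inter-variant distance;
``ld_rho = 0`` gives independent sites. This is a deliberately minimal
stand-in for a coalescent — LD is needed here only as the structure the
mapping works through and the confounder that makes non-causative
variants concordant by hitchhiking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import HaplotypeSet, MarkerPanel, SequenceVariantTable
from .io_formats import write_ebv_table, write_phased_vcf, write_sequence_vcf


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study population.

    Trait units are phenotypic standard deviations: ``qtl_effect`` is the
    per-alt-allele substitution effect and ``h2_polygenic`` the variance
    of the polygenic breeding value, both on that unit scale. The QTL
    site frequency is pinned at ``qtl_freq`` so het/hom classes are both
    populated; all other site frequencies come from a Beta distribution
    truncated to [0.05, 0.95].
    """

    n_animals: int = 300
    n_sequenced: int = 71
    n_seq_variants: int = 1000
    marker_spacing: int = 10
    ld_rho: float = 0.997
    founder_ld_rho: float = 0.9998
    n_founders: int = 30
    maf_alpha: float = 2.0
    maf_beta: float = 2.0
    qtl_variant_index: int = 495
    qtl_freq: float = 0.5
    qtl_effect: float = 0.65
    h2_polygenic: float = 0.25
    r2_low: float = 0.70
    r2_high: float = 0.95
    gq_mean: float = 60.0
    gq_sd: float = 20.0
    genotype_error_rate: float = 0.02
    chrom: str = "1"
    variant_step_bp: int = 6000
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.founder_ld_rho < 1:
            raise ValueError("founder_ld_rho must be in [0, 1)")
        for name in ("qtl_freq", "h2_polygenic", "genotype_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 <= self.r2_low <= self.r2_high < 1:
            raise ValueError("need 0 <= r2_low <= r2_high < 1")
        if self.n_sequenced > self.n_animals:
            raise ValueError("n_sequenced exceeds n_animals")
        if not 0 <= self.qtl_variant_index < self.n_seq_variants:
            raise ValueError("qtl_variant_index out of range")
        if self.qtl_variant_index % self.marker_spacing == 0:
            # the causative site must be sequence-only, never a panel marker
            raise ValueError(
                "qtl_variant_index falls on the marker grid "
                f"(multiples of {self.marker_spacing}); pick an off-grid index"
            )


@dataclass
class SyntheticPopulation:
    """Everything the generator knows about one simulated population."""

    config: SimulationConfig
    variant_panel: MarkerPanel  # all sequence variants
    seq_haps: HaplotypeSet  # truth haplotypes over all sequence variants
    marker_indices: np.ndarray  # indices of panel markers into the variant map
    truth: pd.DataFrame  # animal_id, qtl_genotype, status, true_bv
    ebv: pd.DataFrame  # animal_id, ebv, pi, r2
    sequenced_ids: list = field(default_factory=list)


def _variant_map(cfg: SimulationConfig) -> MarkerPanel:
    pos = (np.arange(cfg.n_seq_variants) + 1) * cfg.variant_step_bp
    table = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "id": [f"var{i:05d}" for i in range(cfg.n_seq_variants)],
            "ref": "A",
            "alt": "G",
        }
    )
    return MarkerPanel(table)


def simulate_haplotypes(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[MarkerPanel, HaplotypeSet]:
    """Draw truth haplotypes for all animals over the full variant map."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    m = cfg.n_seq_variants
    freqs = rng.beta(cfg.maf_alpha, cfg.maf_beta, size=m).clip(0.05, 0.95)
    freqs[cfg.qtl_variant_index] = cfg.qtl_freq

    # founder pool with ancestral LD: latent AR(1) copula, thresholded at
    # each site's allele frequency
    from scipy.stats import norm

    c = cfg.founder_ld_rho
    z = np.empty((cfg.n_founders, m))
    z[:, 0] = rng.standard_normal(cfg.n_founders)
    eps = rng.standard_normal((cfg.n_founders, m))
    for j in range(1, m):
        z[:, j] = c * z[:, j - 1] + math.sqrt(1.0 - c * c) * eps[:, j]
    founders = (z < norm.ppf(freqs)).astype(np.int8)

    n_hap = 2 * cfg.n_animals
    haps = np.empty((n_hap, m), dtype=np.int8)
    # vectorised over haplotypes, sequential over loci
    founder_idx = rng.integers(0, cfg.n_founders, size=n_hap)
    copy_mask = rng.random((n_hap, m)) < cfg.ld_rho
    fresh_draws = (rng.random((n_hap, m)) < freqs).astype(np.int8)
    fresh_founders = rng.integers(0, cfg.n_founders, size=(n_hap, m))
    for j in range(m):
        c = copy_mask[:, j]
        haps[:, j] = np.where(c, founders[founder_idx, j], fresh_draws[:, j])
        founder_idx = np.where(c, founder_idx, fresh_founders[:, j])

    panel = _variant_map(cfg)
    hapset = HaplotypeSet(
        panel=panel,
        animal_ids=[f"A{i:04d}" for i in range(cfg.n_animals)],
        hap1=haps[0::2],
        hap2=haps[1::2],
    )
    return panel, hapset


def assign_phenotypes(
    seq_haps: HaplotypeSet,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True breeding values, noisy EBVs and ground-truth QTL status.

    true BV = qtl_effect * (dosage - mean dosage) + polygenic,
    polygenic ~ N(0, h2_polygenic). The EBV adds noise with variance
    Var(BV) * (1 - r2) / r2, the standard relation between an EBV and its
    reliability; r2 is Uniform(r2_low, r2_high) per animal. All animals
    are founders of the single simulated generation, so the pedigree
    index is 0.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    dos = seq_haps.dosages()[:, cfg.qtl_variant_index].astype(float)
    n = seq_haps.n_animals
    poly = rng.normal(0.0, np.sqrt(cfg.h2_polygenic), size=n)
    bv = cfg.qtl_effect * (dos - dos.mean()) + poly
    var_bv = max(bv.var(), 1e-12)
    r2 = rng.uniform(cfg.r2_low, cfg.r2_high, size=n)
    ebv = bv + rng.normal(0.0, 1.0, size=n) * np.sqrt(var_bv * (1 - r2) / r2)

    truth = pd.DataFrame(
        {
            "animal_id": seq_haps.animal_ids,
            "qtl_genotype": dos.astype(int),
            "status": np.where(dos == 1, "het", "hom"),
            "true_bv": bv,
        }
    )
    ebv_table = pd.DataFrame(
        {"animal_id": seq_haps.animal_ids, "ebv": ebv, "pi": 0.0, "r2": r2}
    )
    return ebv_table, truth


def marker_subset_indices(cfg: SimulationConfig) -> np.ndarray:
    """Panel = every marker_spacing-th variant, excluding the causative one."""
    idx = np.arange(0, cfg.n_seq_variants, cfg.marker_spacing)
    return idx[idx != cfg.qtl_variant_index]


def perturb_sequence_genotypes(
    seq_haps: HaplotypeSet,
    cfg: SimulationConfig,
    sequenced_rows: np.ndarray,
    rng: np.random.Generator | None = None,
) -> SequenceVariantTable:
    """Sequence-variant table for the sequenced subset, with errors and GQ.

    A fraction ``genotype_error_rate`` of genotypes is replaced by one of
    the other two zygosity classes, chosen uniformly. GQ is drawn from
    N(gq_mean, gq_sd), rounded and clipped at 0, independently of whether
    the genotype is wrong — quality scores carry no information about the
    planted errors, so the concordance tolerance, not the GQ gate, has to
    absorb them.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    truth_geno = (
        seq_haps.hap1[sequenced_rows].astype(np.int8)
        + seq_haps.hap2[sequenced_rows].astype(np.int8)
    ).T  # (n_variants, n_sequenced); 0/1/2 == HOM_REF/HET/HOM_ALT
    geno = truth_geno.copy()
    err = rng.random(geno.shape) < cfg.genotype_error_rate
    # wrong class = (true + 1 or 2) mod 3, uniform between the two
    shift = rng.integers(1, 3, size=geno.shape, dtype=np.int8)
    geno[err] = (geno[err] + shift[err]) % 3
    gq = np.rint(rng.normal(cfg.gq_mean, cfg.gq_sd, size=geno.shape))
    gq = np.clip(gq, 0, None).astype(np.int32)
    return SequenceVariantTable(
        variants=seq_haps.panel.table.assign(vtype="SNP"),
        sample_ids=[seq_haps.animal_ids[i] for i in sequenced_rows],
        geno=geno,
        gq=gq,
    )


def simulate_population(cfg: SimulationConfig) -> SyntheticPopulation:
    """Run the full generator with all randomness derived from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    variant_panel, seq_haps = simulate_haplotypes(cfg, rng)
    ebv, truth = assign_phenotypes(seq_haps, cfg, rng)
    sequenced_rows = np.arange(cfg.n_sequenced)
    seq_table = None  # built by emit or on demand
    pop = SyntheticPopulation(
        config=cfg,
        variant_panel=variant_panel,
        seq_haps=seq_haps,
        marker_indices=marker_subset_indices(cfg),
        truth=truth,
        ebv=ebv,
        sequenced_ids=[seq_haps.animal_ids[i] for i in sequenced_rows],
    )
    return pop


def panel_haplotypes(pop: SyntheticPopulation) -> HaplotypeSet:
    """The sparse 50K-like phased panel over all animals."""
    return pop.seq_haps.subset_markers(pop.marker_indices)


def sequence_table(pop: SyntheticPopulation) -> SequenceVariantTable:
    """Perturbed sequence genotypes + GQ for the sequenced subset."""
    rng = np.random.default_rng(pop.config.seed + 2)
    rows = np.arange(pop.config.n_sequenced)
    return perturb_sequence_genotypes(pop.seq_haps, pop.config, rows, rng)


def emit_vcfs(
    pop: SyntheticPopulation,
    panel_vcf: str,
    sequence_vcf: str,
    ebv_tsv: str,
    pedigree_tsv: str | None = None,
    truth_tsv: str | None = None,
) -> None:
    """Write the files the rest of the pipeline consumes."""
    write_phased_vcf(panel_vcf, panel_haplotypes(pop))
    write_sequence_vcf(sequence_vcf, sequence_table(pop))
    write_ebv_table(ebv_tsv, pop.ebv)
    if pedigree_tsv is not None:
        ped = pd.DataFrame(
            {"animal_id": pop.seq_haps.animal_ids, "sire_id": "0", "dam_id": "0"}
        )
        ped.to_csv(pedigree_tsv, sep="\t", index=False)
    if truth_tsv is not None:
        pop.truth.to_csv(truth_tsv, sep="\t", index=False, float_format="%.10g")
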