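"""Concordance of sequence variants with inferred QTL statuses.

A causative variant must be heterozygous in every QTL-heterozygous
animal and homozygous (for either allele) in every QTL-homozygous animal,
up to status and sequencing errors. Each variant is compared against the
status calls over the animals that pass the genotype-quality gate; the
probability that an unlinked variant matches by chance across n
heterozygous and m homozygous comparisons, integrated over its unknown
allele frequency p, is

    p_c = integral_0^1 [2p(1-p)]^n [1 - 2p(1-p)]^m dp.

A variant is kept as a candidate causative mutation iff
  1. at least ``fraction_min`` (default 90%) of compared animals are
     concordant,
  2. at least 5 homozygous and 5 heterozygous animals could be compared
     (GQ >= 20), and
  3. p_c < 1 / (number of variants in the region).
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy import integrate

from .datatypes import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    STATUS_HET,
    STATUS_HOM,
    SequenceVariantTable,
)

_EXACT_LIMIT = 400  # n+m beyond which exact rationals give way to quadrature


def pc_exact(n: int, m: int) -> float:
    """Chance-concordance probability by exact binomial expansion.

    Expanding (1 - 2p(1-p))^m and integrating term by term:

        p_c = 2^n * sum_{j=0}^{m} C(m,j) (-2)^j B(n+j+1, n+j+1)

    with B(a,a) = (a-1)!^2 / (2a-1)!. The alternating series cancels
    catastrophically in floats, so it is summed in exact rationals.
    """
    if n < 0 or m < 0:
        raise ValueError("counts must be non-negative")
    if n + m > _EXACT_LIMIT:
        return pc_quadrature(n, m)
    total = Fraction(0)
    for j in range(m + 1):
        a = n + j + 1
        beta = Fraction(factorial(a - 1) ** 2, factorial(2 * a - 1))
        total += comb(m, j) * Fraction(-2) ** j * beta
    return float(Fraction(2) ** n * total)


def pc_quadrature(n: int, m: int, tol: float = 1e-12) -> float:
    """Independent numerical evaluation by adaptive quadrature."""
    if n < 0 or m < 0:
        raise ValueError("counts must be non-negative")

    def integrand(p):
        f = 2.0 * p * (1.0 - p)
        return f**n * (1.0 - f) ** m

    val, err = integrate.quad(integrand, 0.0, 1.0, epsabs=0.0, epsrel=tol, limit=200)
    if val > 0 and err / val > 1e-6:
        raise RuntimeError(f"quadrature tolerance not reached for n={n}, m={m}")
    return val


def compare_variant(
    geno: np.ndarray,
    gq: np.ndarray,
    status: np.ndarray,
    gq_min: int = 20,
) -> dict:
    """Compare one variant's genotypes against QTL statuses.

    Arrays are aligned over the same animals. An animal contributes iff
    its status is hom or het, its genotype is non-missing, and GQ >=
    gq_min. Concordant means het-status with a het genotype, or
    hom-status with a homozygous genotype (either allele).

    Returns n (het compared), m (hom compared), c (concordant) and the
    concordant fraction (NaN when nothing could be compared).
    """
    geno = np.asarray(geno)
    gq = np.asarray(gq)
    status = np.asarray(status, dtype=object)
    if not (geno.shape == gq.shape == status.shape):
        raise ValueError("geno, gq and status must align")
    informative = (status == STATUS_HOM) | (status == STATUS_HET)
    if not informative.any():
        raise ValueError("no animals with called QTL status to compare")
    use = informative & (geno != MISSING) & (gq >= gq_min)
    het_s = use & (status == STATUS_HET)
    hom_s = use & (status == STATUS_HOM)
    n = int(het_s.sum())
    m = int(hom_s.sum())
    conc = int((het_s & (geno == HET)).sum()) + int(
        (hom_s & ((geno == HOM_REF) | (geno == HOM_ALT))).sum()
    )
    frac = conc / (n + m) if (n + m) else float("nan")
    return {"n": n, "m": m, "c": conc, "fraction": frac}


def concordance_table(
    seq: SequenceVariantTable,
    status_calls: pd.DataFrame,
    gq_min: int = 20,
) -> pd.DataFrame:
    """Per-variant comparison counts and p_c over a region's variants.

    ``status_calls`` must have animal_id and status columns; animals not
    sequenced are ignored, sequenced animals without a call contribute
    nothing.
    """
    status_by_id = dict(
        zip(status_calls["animal_id"].astype(str), status_calls["status"])
    )
    status = np.array(
        [status_by_id.get(str(s), "unknown") for s in seq.sample_ids], dtype=object
    )
    if not np.isin(status, [STATUS_HOM, STATUS_HET]).any():
        raise ValueError("status calls share no hom/het animals with the VCF samples")
    rows = []
    pc_cache: dict[tuple, float] = {}
    for i in range(seq.n_variants):
        cmp = compare_variant(seq.geno[i], seq.gq[i], status, gq_min=gq_min)
        key = (cmp["n"], cmp["m"])
        if key not in pc_cache:
            pc_cache[key] = pc_exact(*key)
        cmp["p_c"] = pc_cache[key]
        rows.append(cmp)
    out = seq.variants[["chrom", "pos", "id", "ref", "alt", "vtype"]].copy()
    return pd.concat([out, pd.DataFrame(rows)], axis=1)


def concordance_filter(
    results: pd.DataFrame,
    n_poly: int,
    fraction_min: float = 0.90,
    min_het: int = 5,
    min_hom: int = 5,
) -> pd.DataFrame:
    """Apply the three candidate filters; annotate per-criterion outcomes.

    Adds boolean columns passes_fraction / passes_counts / passes_pc and
    `concordant` (their conjunction), plus a fail_reasons column naming
    the violated criteria.
    """
    if n_poly <= 0:
        raise ValueError("n_poly must be positive")
    out = results.copy()
    frac = out["fraction"].to_numpy(dtype=float)
    out["passes_fraction"] = ~np.isnan(frac) & (frac >= fraction_min)
    out["passes_counts"] = (out["n"] >= min_het) & (out["m"] >= min_hom)
    out["passes_pc"] = out["p_c"] < 1.0 / n_poly
    out["concordant"] = (
        out["passes_fraction"] & out["passes_counts"] & out["passes_pc"]
    )
    reasons = []
    for _, r in out.iterrows():
        rs = []
        if not r["passes_fraction"]:
            rs.append("fraction")
        if not r["passes_counts"]:
            rs.append("counts")
        if not r["passes_pc"]:
            rs.append("pc")
        reasons.append(",".join(rs) if rs else "")
    out["fail_reasons"] = reasons
    return out


def sweep_tolerance(
    results: pd.DataFrame,
    n_poly: int,
    fractions=None,
    min_het: int = 5,
    min_hom: int = 5,
) -> pd.DataFrame:
    """Concordant-variant counts as the allowed error fraction shrinks.

    Default grid runs the threshold from 0.90 up to 1.00 in steps of
    0.01; counts are non-increasing along the grid by construction.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.90, 1.0001, 0.01), 2)
    rows = []
    for f in fractions:
        filt = concordance_filter(
            results, n_poly, fraction_min=float(f), min_het=min_het, min_hom=min_hom
        )
        rows.append((float(f), int(filt["concordant"].sum())))
    return pd.DataFrame(rows, columns=["fraction_min", "n_concordant"])


def annotate_join(
    concordant: pd.DataFrame, annotation: pd.DataFrame | None
) -> pd.DataFrame:
    """Left-join a pre-computed consequence-class table onto variants.

    Keys are (chrom, pos, ref, alt); unannotated variants get the class
    'unannotated'; duplicate annotation keys keep the first occurrence.
    """
    out = concordant.copy()
    if annotation is None or annotation.empty:
        out["consequence"] = "unannotated"
        return out
    ann = annotation.copy()
    ann["chrom"] = ann["chrom"].astype(str)
    dup = ann.duplicated(subset=["chrom", "pos", "ref", "alt"])
    if dup.any():
        import warnings

        warnings.warn(f"{int(dup.sum())} duplicate annotation keys; first wins")
        ann = ann[~dup]
    out["chrom"] = out["chrom"].astype(str)
    merged = out.merge(
        ann[["chrom", "pos", "ref", "alt", "consequence"]],
        on=["chrom", "pos", "ref", "alt"],
        how="left",
    )
    merged["consequence"] = merged["consequence"].fillna("unannotated")
    return merged


def consequence_counts(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts of concordant variants (report convenience)."""
    kept = annotated[annotated.get("concordant", True)]
    counts = kept["consequence"].value_counts().sort_index()
    return counts.rename_axis("consequence").reset_index(name="count")
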