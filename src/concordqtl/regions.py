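"""Window-based QTL region selection from posterior inclusion probabilities.

The genome is scanned with sliding windows of L adjacent markers (never
spanning a chromosome break); windows are ranked by the sum of per-marker
posterior inclusion probabilities (sum-p) and selected greedily so that no
two chosen regions share a marker. Within a selected region the
best contiguous sub-interval of L' markers (L' = 10, 20, 30) is the block
maximising its sum-p, used downstream for status inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import HaplotypeSet, MarkerPanel, QTLRegion


def maf_filter(haps: HaplotypeSet, threshold: float = 0.05):
    """Drop markers with minor allele frequency below threshold.

    Returns (filtered HaplotypeSet, kept global indices).
    """
    freq = (haps.hap1.mean(axis=0) + haps.hap2.mean(axis=0)) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.flatnonzero(maf >= threshold)
    return haps.subset_markers(keep), keep


def window_sums(panel: MarkerPanel, p: np.ndarray, L: int = 40) -> pd.DataFrame:
    """Sliding-window sums of p over L adjacent markers per chromosome.

    A chromosome with fewer than L markers contributes a single window
    covering all of it. Columns: chrom, start_idx, end_idx (global,
    inclusive), sum_p.
    """
    p = np.asarray(p, dtype=float)
    if p.shape[0] != panel.n_markers:
        raise ValueError("p length does not match panel")
    rows = []
    for chrom, (lo, hi) in panel.chrom_ranges().items():
        nc = hi - lo
        if nc <= L:
            rows.append((chrom, lo, hi - 1, float(p[lo:hi].sum())))
            continue
        csum = np.concatenate([[0.0], np.cumsum(p[lo:hi])])
        sums = csum[L:] - csum[:-L]
        for s, v in enumerate(sums):
            rows.append((chrom, lo + s, lo + s + L - 1, float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start_idx", "end_idx", "sum_p"])


def select_regions(
    windows: pd.DataFrame, panel: MarkerPanel, K: int = 20
) -> list[QTLRegion]:
    """Greedy top-K non-overlapping windows by sum_p.

    Repeatedly takes the highest-sum_p window sharing no marker with an
    already selected one; ties break by (chromosome, start) order.
    """
    w = windows.sort_values(
        by=["sum_p", "chrom", "start_idx"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    pos = panel.table["pos"].to_numpy()
    taken: list[tuple] = []
    out: list[QTLRegion] = []
    for _, row in w.iterrows():
        if len(out) >= K:
            break
        s, e = int(row.start_idx), int(row.end_idx)
        if any(not (e < ts or s > te) for ts, te in taken):
            continue
        taken.append((s, e))
        out.append(
            QTLRegion(
                chrom=row.chrom,
                start_idx=s,
                end_idx=e,
                start_bp=int(pos[s]),
                end_bp=int(pos[e]),
                sum_p=float(row.sum_p),
                rank=len(out),
            )
        )
    return out


def best_subinterval(region: QTLRegion, p: np.ndarray, L_sub: int) -> tuple[int, int, float]:
    """Contiguous block of L_sub markers in the region maximising sum-p.

    Ties resolve to the leftmost block. Returns global (start_idx,
    end_idx, sum_p).
    """
    n = region.n_markers
    if L_sub > n:
        raise ValueError(f"sub-interval length {L_sub} exceeds region length {n}")
    pr = np.asarray(p, dtype=float)[region.start_idx : region.end_idx + 1]
    # direct per-block summation: identical blocks give identical floats,
    # so the leftmost-tie rule is not disturbed by cumsum rounding
    sums = np.convolve(pr, np.ones(L_sub), mode="valid")
    s = int(np.argmax(sums))  # argmax takes the first (leftmost) maximum
    return region.start_idx + s, region.start_idx + s + L_sub - 1, float(sums[s])


def attach_subintervals(
    regions: list[QTLRegion], p: np.ndarray, lengths=(10, 20, 30)
) -> list[QTLRegion]:
    for r in regions:
        for L_sub in lengths:
            if L_sub <= r.n_markers:
                r.subintervals[L_sub] = best_subinterval(r, p, L_sub)
    return regions


def regions_table(regions: list[QTLRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        row = {
            "rank": r.rank,
            "chrom": r.chrom,
            "start_idx": r.start_idx,
            "end_idx": r.end_idx,
            "start_bp": r.start_bp,
            "end_bp": r.end_bp,
            "sum_p": r.sum_p,
        }
        for L_sub, (_, _, sp) in sorted(r.subintervals.items(), reverse=True):
            row[f"sum_p_{L_sub}"] = sp
        rows.append(row)
    return pd.DataFrame(rows)


def cross_trait_overlap(
    regions: list[QTLRegion],
    trait_p: dict,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """For each region, which other traits exceed the sum-p threshold.

    ``trait_p`` maps trait name -> per-marker inclusion probabilities on
    the same (filtered) panel the regions were selected on.
    """
    rows = []
    for r in regions:
        for trait, p in trait_p.items():
            p = np.asarray(p, dtype=float)
            if p.shape[0] <= r.end_idx:
                raise ValueError(
                    f"trait {trait!r} probabilities do not cover the panel"
                )
            sp = float(p[r.start_idx : r.end_idx + 1].sum())
            if sp >= threshold:
                rows.append((r.rank, r.chrom, r.start_bp, r.end_bp, trait, sp))
    return pd.DataFrame(
        rows, columns=["rank", "chrom", "start_bp", "end_bp", "trait", "sum_p"]
    )
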