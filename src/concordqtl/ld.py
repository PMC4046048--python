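"""Lewontin's D' from phased haplotypes (region diagnostics).

With phased input the gametic frequencies are observed directly, so D'
is computed from haplotype counts — no EM frequency estimation:

    D = f(AB) - f(A) f(B)
    D' = D / D_max,  D_max = min(f(A) f(b), f(a) f(B))   if D > 0
                     D_max = min(f(A) f(B), f(a) f(b))   if D < 0

D' is undefined (NaN) when either locus is monomorphic; D = 0 gives
D' = 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import HaplotypeSet, QTLRegion


def dprime(alleles_a: np.ndarray, alleles_b: np.ndarray) -> tuple[float, float]:
    """(D, D') from paired haplotype alleles at two loci (0/1 coded)."""
    a = np.asarray(alleles_a, dtype=float).ravel()
    b = np.asarray(alleles_b, dtype=float).ravel()
    if a.shape != b.shape or a.shape[0] < 2:
        raise ValueError("need >= 2 paired haplotypes")
    pA = a.mean()
    pB = b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return float("nan"), float("nan")
    d = float((a * b).mean() - pA * pB)
    if d > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    elif d < 0:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        return 0.0, 0.0
    return d, d / d_max


def region_ld(haps: HaplotypeSet, region: QTLRegion | np.ndarray) -> pd.DataFrame:
    """All pairwise D' within a region, long format (i, j, D, Dprime).

    ``region`` may be a QTLRegion or an explicit array of global marker
    indices. i/j are global marker indices with i < j.
    """
    if isinstance(region, QTLRegion):
        idx = region.marker_indices()
    else:
        idx = np.asarray(region)
    alleles = np.concatenate([haps.hap1[:, idx], haps.hap2[:, idx]], axis=0)
    rows = []
    for ii in range(idx.shape[0]):
        for jj in range(ii + 1, idx.shape[0]):
            d, dp = dprime(alleles[:, ii], alleles[:, jj])
            rows.append((int(idx[ii]), int(idx[jj]), d, dp))
    return pd.DataFrame(rows, columns=["i", "j", "D", "Dprime"])


def mean_abs_dprime_by_lag(haps: HaplotypeSet, max_lag: int = 20) -> pd.DataFrame:
    """Mean |D'| between marker pairs at each index lag (LD-decay profile)."""
    alleles = np.concatenate([haps.hap1, haps.hap2], axis=0)
    m = alleles.shape[1]
    rows = []
    for lag in range(1, max_lag + 1):
        vals = []
        for i in range(m - lag):
            _, dp = dprime(alleles[:, i], alleles[:, i + lag])
            if not np.isnan(dp):
                vals.append(abs(dp))
        rows.append((lag, float(np.mean(vals)) if vals else float("nan")))
    return pd.DataFrame(rows, columns=["lag", "mean_abs_dprime"])
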