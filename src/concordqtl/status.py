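"""QTL status calls from haplotype effects via k-medoids clustering.

Each animal's two phased haplotypes are scored by summing estimated
marker effects over the alt alleles they carry (H = sum over carried-alt
markers of a_hat). The absolute difference d = |H1 - H2| separates
homozygous (d near 0) from heterozygous carriers (d near the QTL
substitution effect). Animals are grouped on d with PAM (partitioning
around medoids, Euclidean distance, best-improvement swaps, multiple
random restarts); k in {2, 3, 4} is picked by the best average
silhouette. The cluster with the lowest mean d is called homozygous, the
highest heterozygous, any others unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import (
    STATUS_HET,
    STATUS_HOM,
    STATUS_UNKNOWN,
    HaplotypeSet,
    QTLRegion,
)


@dataclass
class Clustering:
    """A PAM solution on 1-D points."""

    k: int
    medoid_idx: np.ndarray  # indices into the point array
    labels: np.ndarray  # medoid slot per point
    cost: float  # sum of |x_i - medoid(x_i)|

    @property
    def medoids(self) -> np.ndarray:
        return self._points[self.medoid_idx]

    def attach(self, points: np.ndarray) -> "Clustering":
        self._points = points
        return self


def haplotype_effect(
    haplotype: np.ndarray, a_hat: np.ndarray, marker_subset: np.ndarray | None = None
) -> float:
    """H = sum over the subset of (alt-allele indicator) * a_hat."""
    h = np.asarray(haplotype, dtype=float)
    a = np.asarray(a_hat, dtype=float)
    if marker_subset is not None:
        idx = np.asarray(marker_subset)
        if idx.size and (idx.min() < 0 or idx.max() >= h.shape[0]):
            raise IndexError("marker subset outside haplotype range")
        h, a = h[idx], a[idx]
    return float(h @ a)


def _assign(points: np.ndarray, medoids: np.ndarray):
    d = np.abs(points[:, None] - medoids[None, :])
    labels = np.argmin(d, axis=1)
    cost = float(d[np.arange(points.shape[0]), labels].sum())
    return labels, cost


def pam(
    points: np.ndarray, k: int, seed: int = 0, restarts: int = 10
) -> Clustering:
    """Partitioning around medoids on 1-D data.

    Each restart starts from k distinct random medoids, then repeats
    best-improvement (medoid, non-medoid) swaps until no swap lowers the
    total Euclidean cost; the lowest-cost restart wins.
    """
    x = np.asarray(points, dtype=float).ravel()
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of points {n}")
    distinct = np.unique(x)
    if k > distinct.shape[0]:
        raise ValueError(f"k={k} exceeds number of distinct points")
    rng = np.random.default_rng(seed)
    best = None
    absdiff = np.abs(x[:, None] - x[None, :])
    for _ in range(restarts):
        # sample distinct values, then map back to point indices
        vals = rng.choice(distinct, size=k, replace=False)
        med = np.array([int(np.argmax(x == v)) for v in vals])
        _, cost = _assign(x, x[med])
        improved = True
        while improved:
            improved = False
            # column mins over current medoids, for fast swap evaluation
            for slot in range(k):
                others = np.delete(med, slot)
                d_others = (
                    absdiff[:, others].min(axis=1)
                    if others.size
                    else np.full(n, np.inf)
                )
                # candidate replacement for this slot: any non-medoid point
                cand_cost = np.minimum(d_others[:, None], absdiff).sum(axis=0)
                cand_cost[med] = np.inf
                j = int(np.argmin(cand_cost))
                if cand_cost[j] < cost - 1e-12:
                    med[slot] = j
                    cost = float(cand_cost[j])
                    improved = True
        if best is None or cost < best.cost - 1e-12:
            labels, cost = _assign(x, x[med])
            best = Clustering(k=k, medoid_idx=med.copy(), labels=labels, cost=cost)
    return best.attach(x)


def avg_silhouette(points: np.ndarray, clustering: Clustering) -> float:
    """Average silhouette width with Euclidean distance on 1-D points.

    A point in a singleton cluster contributes 0 (convention for
    undefined within-cluster distance).
    """
    x = np.asarray(points, dtype=float).ravel()
    labels = clustering.labels
    k = clustering.k
    if k < 2:
        raise ValueError("silhouette requires k >= 2")
    n = x.shape[0]
    absdiff = np.abs(x[:, None] - x[None, :])
    s = np.zeros(n)
    sizes = np.bincount(labels, minlength=k)
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        a_i = absdiff[i, labels == own].sum() / (sizes[own] - 1)
        b_i = min(
            absdiff[i, labels == c].mean() for c in range(k) if c != own and sizes[c]
        )
        denom = max(a_i, b_i)
        s[i] = 0.0 if denom == 0 else (b_i - a_i) / denom
    return float(s.mean())


def choose_k(
    points: np.ndarray, seed: int = 0, ks=(2, 3, 4), restarts: int = 10
):
    """Pick k among {2,3,4} by maximal average silhouette (ties -> smallest).

    Returns (k, {k: (Clustering, silhouette)}). Degenerate inputs with
    fewer than 4 distinct values fall back to k=2 with a warning.
    """
    x = np.asarray(points, dtype=float).ravel()
    n_distinct = np.unique(x).shape[0]
    if n_distinct < 2:
        raise ValueError("need at least 2 distinct values to cluster")
    if n_distinct < 4:
        warnings.warn(
            f"only {n_distinct} distinct values; falling back to k=2",
            stacklevel=2,
        )
        cl = pam(x, 2, seed=seed + 2, restarts=restarts)
        return 2, {2: (cl, avg_silhouette(x, cl))}
    results = {}
    for k in ks:
        cl = pam(x, k, seed=seed + k, restarts=restarts)
        results[k] = (cl, avg_silhouette(x, cl))
    best_k = max(results, key=lambda k: (results[k][1], -k))
    return best_k, results


def assign_status(points: np.ndarray, clustering: Clustering) -> np.ndarray:
    """Label clusters: lowest mean d -> hom, highest -> het, rest unknown."""
    x = np.asarray(points, dtype=float).ravel()
    labels = clustering.labels
    means = np.array(
        [
            x[labels == c].mean() if np.any(labels == c) else np.inf
            for c in range(clustering.k)
        ]
    )
    hom_c = int(np.argmin(means))
    het_c = int(np.argmax(means))
    status = np.full(x.shape[0], STATUS_UNKNOWN, dtype=object)
    status[labels == hom_c] = STATUS_HOM
    status[labels == het_c] = STATUS_HET
    return status


def infer_status(
    region: QTLRegion,
    a_hat: np.ndarray,
    haps: HaplotypeSet,
    interval_mode: int = 10,
    seed: int = 0,
    restarts: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Full status inference for one region.

    ``interval_mode`` selects the marker set for haplotype effects: the
    whole region when it equals the region length (or no sub-interval is
    attached), else the attached best sub-interval of that length.

    Returns (status table, diagnostics). The table has one row per
    animal: animal_id, H1, H2, d, cluster, status. If every d is
    identical (e.g. all effects zero) no grouping is possible and all
    statuses are unknown.
    """
    if interval_mode in region.subintervals:
        idx = region.marker_indices(interval_mode)
    else:
        idx = region.marker_indices()
    a = np.asarray(a_hat, dtype=float)[idx]
    H1 = haps.hap1[:, idx].astype(float) @ a
    H2 = haps.hap2[:, idx].astype(float) @ a
    d = np.abs(H1 - H2)
    base = pd.DataFrame(
        {"animal_id": haps.animal_ids, "H1": H1, "H2": H2, "d": d}
    )
    if np.unique(d).shape[0] < 2:
        warnings.warn(
            "degenerate haplotype differences (all equal); statuses unknown",
            stacklevel=2,
        )
        base["cluster"] = 0
        base["status"] = STATUS_UNKNOWN
        return base, {"k": None, "silhouettes": {}, "degenerate": True}
    k, results = choose_k(d, seed=seed, restarts=restarts)
    clustering = results[k][0]
    base["cluster"] = clustering.labels
    base["status"] = assign_status(d, clustering)
    diagnostics = {
        "k": k,
        "silhouettes": {kk: sil for kk, (_, sil) in results.items()},
        "cluster_means": {
            int(c): float(d[clustering.labels == c].mean())
            for c in range(k)
            if np.any(clustering.labels == c)
        },
        "degenerate": False,
        "interval_markers": idx.tolist(),
    }
    return base, diagnostics
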