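import itertools

import numpy as np
import pytest

from concordqtl import simulate as sim
from concordqtl.datatypes import QTLRegion
from concordqtl.status import (
    assign_status,
    avg_silhouette,
    choose_k,
    haplotype_effect,
    infer_status,
    pam,
)


def exhaustive_pam_cost(x, k):
    """Global optimum over all medoid subsets (reference oracle)."""
    n = len(x)
    best = np.inf
    for med in itertools.combinations(range(n), k):
        cost = sum(min(abs(xi - x[j]) for j in med) for xi in x)
        best = min(best, cost)
    return best


class TestHaplotypeEffect:
    def test_zero_effects(self):
        assert haplotype_effect([1, 1, 0], np.zeros(3)) == 0.0

    def test_alt_alleles_only_counted(self):
        h = [1, 0, 1]
        a = [0.5, 9.0, 0.25]
        assert haplotype_effect(h, a) == pytest.approx(0.75)
        assert haplotype_effect(h, a, marker_subset=[1, 2]) == pytest.approx(0.25)

    def test_out_of_range_subset_rejected(self):
        with pytest.raises(IndexError):
            haplotype_effect([1, 0], [0.5, 0.5], marker_subset=[5])


class TestPam:
    def test_two_tight_pairs(self):
        cl = pam(np.array([0.0, 0.1, 5.0, 5.1]), k=2, seed=1)
        assert cl.cost == pytest.approx(0.2)
        assert len(set(cl.labels[:2])) == 1 and len(set(cl.labels[2:])) == 1

    def test_k_equals_n_zero_cost(self):
        cl = pam(np.array([1.0, 2.0, 3.0]), k=3, seed=0)
        assert cl.cost == 0.0

    def test_duplicate_heavy(self):
        cl = pam(np.array([1.0, 1.0, 1.0, 9.0]), k=2, seed=0)
        assert cl.cost == 0.0
        assert sorted(np.unique(cl.medoids)) == [1.0, 9.0]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            pam(np.array([1.0, 2.0]), k=3, seed=0)

    def test_attains_exhaustive_optimum(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, 5))
            x = np.round(rng.random(n) * 10, 4)
            if len(np.unique(x)) < k:
                continue
            cl = pam(x, k=k, seed=7, restarts=10)
            assert cl.cost == pytest.approx(exhaustive_pam_cost(x, k), abs=1e-9)


class TestSilhouette:
    def test_well_separated_pairs_near_one(self):
        x = np.array([0.0, 0.01, 10.0, 10.01])
        cl = pam(x, k=2, seed=0)
        assert avg_silhouette(x, cl) > 0.99

    def test_arbitrary_split_of_identical_points_not_positive(self):
        from concordqtl.status import Clustering

        x = np.array([1.0, 1.0, 1.0, 1.0])
        cl = Clustering(
            k=2,
            medoid_idx=np.array([0, 2]),
            labels=np.array([0, 0, 1, 1]),
            cost=0.0,
        ).attach(x)
        assert avg_silhouette(x, cl) <= 0.0

    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import silhouette_score

        for _ in range(10):
            x = rng.normal(size=30)
            cl = pam(x, k=3, seed=2)
            if len(np.unique(cl.labels)) < 2 or np.bincount(cl.labels).min() < 2:
                continue
            ours = avg_silhouette(x, cl)
            ref = silhouette_score(x.reshape(-1, 1), cl.labels)
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_single_cluster_rejected(self):
        x = np.array([1.0, 2.0])
        cl = pam(x, k=1, seed=0) if False else None
        from concordqtl.status import Clustering

        cl = Clustering(k=1, medoid_idx=np.array([0]), labels=np.zeros(2, int), cost=1.0).attach(x)
        with pytest.raises(ValueError):
            avg_silhouette(x, cl)


class TestChooseK:
    def test_three_groups_detected(self, rng):
        x = np.concatenate(
            [rng.normal(0, 0.05, 20), rng.normal(5, 0.05, 20), rng.normal(10, 0.05, 20)]
        )
        k, _ = choose_k(x, seed=3)
        assert k == 3

    def test_two_groups_detected(self, rng):
        x = np.concatenate([rng.normal(0, 0.05, 25), rng.normal(5, 0.05, 25)])
        k, _ = choose_k(x, seed=3)
        assert k == 2

    def test_deterministic(self, rng):
        x = rng.normal(size=40)
        assert choose_k(x, seed=9)[0] == choose_k(x, seed=9)[0]

    def test_degenerate_input_falls_back_to_two(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="distinct"):
            k, _ = choose_k(x, seed=0)
        assert k == 2


class TestAssignStatus:
    def test_two_clusters_low_hom_high_het(self):
        x = np.array([0.0, 0.05, 1.0, 1.05])
        cl = pam(x, k=2, seed=0)
        status = assign_status(x, cl)
        assert list(status[:2]) == ["hom", "hom"]
        assert list(status[2:]) == ["het", "het"]

    def test_middle_cluster_unknown(self):
        x = np.array([0.0, 0.01, 0.5, 0.51, 1.0, 1.01])
        cl = pam(x, k=3, seed=0)
        status = assign_status(x, cl)
        assert sorted(set(status)) == ["het", "hom", "unknown"]
        assert list(status[2:4]) == ["unknown", "unknown"]

    def test_partition_covers_all(self, rng):
        x = rng.normal(size=50)
        cl = pam(x, k=4, seed=1)
        status = assign_status(x, cl)
        assert len(status) == 50
        assert set(status) <= {"hom", "het", "unknown"}


class TestInferStatus:
    def _setup(self, pop):
        from concordqtl.regions import attach_subintervals

        haps = sim.panel_haplotypes(pop)
        qi = pop.config.qtl_variant_index
        # oracle effects: regression of the causative allele on the six
        # nearest panel markers over all truth haplotypes (tests the
        # status machinery independently of the mapping chain)
        a_hat = np.zeros(haps.panel.n_markers)
        marker_of = {v: i for i, v in enumerate(pop.marker_indices)}
        spacing = pop.config.marker_spacing
        left = qi - (qi % spacing)
        near = [left + d * spacing for d in (-2, -1, 0, 1, 2, 3)]
        cols = [marker_of[v] for v in near if v in marker_of]
        X = np.concatenate([haps.hap1, haps.hap2], axis=0)[:, cols].astype(float)
        y = np.concatenate(
            [pop.seq_haps.hap1[:, qi], pop.seq_haps.hap2[:, qi]]
        ).astype(float)
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None
        )
        a_hat[cols] = coef[1:]
        lo = max(0, marker_of[left] - 19)
        region = QTLRegion(
            chrom=pop.config.chrom,
            start_idx=lo,
            end_idx=min(haps.panel.n_markers - 1, lo + 39),
            start_bp=int(haps.panel.table["pos"].iloc[lo]),
            end_bp=int(haps.panel.table["pos"].iloc[min(haps.panel.n_markers - 1, lo + 39)]),
            sum_p=1.0,
            rank=0,
        )
        attach_subintervals(region and [region], a_hat / 2)
        return haps, a_hat, region

    def test_truth_recovery_with_oracle_effects(self):
        hits = total = 0
        for seed in (7, 8, 9):
            cfg = sim.SimulationConfig(
                n_animals=120, n_sequenced=60, n_seq_variants=400,
                qtl_variant_index=195, seed=seed,
            )
            pop = sim.simulate_population(cfg)
            haps, a_hat, region = self._setup(pop)
            calls, _ = infer_status(region, a_hat, haps, interval_mode=10, seed=5)
            merged = calls.merge(pop.truth, on="animal_id")
            called = merged[merged["status_x"].isin(["hom", "het"])]
            hits += int((called["status_x"] == called["status_y"]).sum())
            total += len(called)
        assert hits / total > 0.85

    def test_all_zero_effects_degenerate(self, small_pop):
        haps, a_hat, region = self._setup(small_pop)
        with pytest.warns(UserWarning, match="degenerate"):
            calls, diag = infer_status(region, np.zeros_like(a_hat), haps, seed=5)
        assert (calls["status"] == "unknown").all()
        assert diag["degenerate"]

    def test_subinterval_wiring(self, small_pop):
        haps, a_hat, region = self._setup(small_pop)
        calls, diag = infer_status(region, a_hat, haps, interval_mode=10, seed=5)
        assert diag["interval_markers"] == region.marker_indices(10).tolist()
        assert len(diag["interval_markers"]) == 10

    def test_animal_order_invariance(self, small_pop):
        from concordqtl.datatypes import HaplotypeSet

        haps, a_hat, region = self._setup(small_pop)
        perm = np.random.default_rng(0).permutation(haps.n_animals)
        shuffled = HaplotypeSet(
            panel=haps.panel,
            animal_ids=[haps.animal_ids[i] for i in perm],
            hap1=haps.hap1[perm],
            hap2=haps.hap2[perm],
        )
        c1, _ = infer_status(region, a_hat, haps, interval_mode=10, seed=5)
        c2, _ = infer_status(region, a_hat, shuffled, interval_mode=10, seed=5)
        m = c1.merge(c2, on="animal_id", suffixes=("_a", "_b"))
        assert (m["status_a"] == m["status_b"]).all()

    def test_het_rate_increases_with_qtl_maf(self):
        rates = []
        for freq in (0.1, 0.3, 0.5):
            per_seed = []
            for seed in (21, 22, 23, 24, 25):
                cfg = sim.SimulationConfig(
                    n_animals=150, n_sequenced=50, n_seq_variants=400,
                    qtl_variant_index=195, qtl_freq=freq, seed=seed,
                )
                pop = sim.simulate_population(cfg)
                haps, a_hat, region = self._setup(pop)
                calls, _ = infer_status(region, a_hat, haps, interval_mode=10, seed=5)
                per_seed.append((calls["status"] == "het").mean())
            rates.append(np.mean(per_seed))
        assert rates[0] < rates[1] < rates[2]
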