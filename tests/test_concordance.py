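from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from concordqtl.concordance import (
    annotate_join,
    compare_variant,
    concordance_filter,
    concordance_table,
    pc_exact,
    pc_quadrature,
    sweep_tolerance,
)
from concordqtl.datatypes import HET, HOM_ALT, HOM_REF, MISSING


class TestPcExact:
    @pytest.mark.parametrize(
        "n, m, expected",
        [
            (0, 0, Fraction(1)),
            (1, 0, Fraction(1, 3)),
            (0, 1, Fraction(2, 3)),
            (1, 1, Fraction(1, 5)),  # 1/3 - 4 B(3,3)
            (5, 5, Fraction(8, 13923)),  # sympy-verified closed form
        ],
    )
    def test_closed_form_anchors(self, n, m, expected):
        assert pc_exact(n, m) == pytest.approx(float(expected), rel=1e-14)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pc_exact(-1, 0)
        with pytest.raises(ValueError):
            pc_quadrature(0, -2)

    def test_agrees_with_quadrature(self):
        for n in range(0, 13, 3):
            for m in range(0, 13, 3):
                e = pc_exact(n, m)
                q = pc_quadrature(n, m)
                assert abs(e - q) <= 1e-10 * max(e, q)

    def test_strictly_decreasing_in_each_count(self):
        for n in range(0, 15):
            assert pc_exact(n + 1, 3) < pc_exact(n, 3)
            assert pc_exact(3, n + 1) < pc_exact(3, n)

    def test_integrand_symmetric_about_half(self):
        # p <-> 1-p leaves 2p(1-p) invariant: the two half-integrals agree
        n, m = 4, 7

        def f(p):
            g = 2 * p * (1 - p)
            return g**n * (1 - g) ** m

        left, _ = integrate.quad(f, 0.0, 0.5)
        right, _ = integrate.quad(f, 0.5, 1.0)
        assert left == pytest.approx(right, rel=1e-10)
        assert left + right == pytest.approx(pc_exact(n, m), rel=1e-10)


class TestCompareVariant:
    def _arrays(self, geno, gq, status):
        return np.array(geno), np.array(gq), np.array(status, dtype=object)

    def test_fully_concordant(self):
        geno = [HOM_ALT] * 5 + [HET] * 5
        gq = [30] * 10
        status = ["hom"] * 5 + ["het"] * 5
        out = compare_variant(*self._arrays(geno, gq, status))
        assert (out["n"], out["m"], out["c"], out["fraction"]) == (5, 5, 10, 1.0)

    def test_low_gq_excluded(self):
        geno = [HOM_ALT] * 5 + [HET] * 5
        gq = [30] * 9 + [10]
        status = ["hom"] * 5 + ["het"] * 5
        out = compare_variant(*self._arrays(geno, gq, status))
        assert (out["n"], out["m"], out["c"]) == (4, 5, 9)

    def test_one_discordant(self):
        geno = [HOM_ALT] * 4 + [HET] + [HET] * 5
        gq = [30] * 10
        status = ["hom"] * 5 + ["het"] * 5
        out = compare_variant(*self._arrays(geno, gq, status))
        assert out["c"] == 9 and out["fraction"] == pytest.approx(0.9)

    def test_hom_either_allele_concordant(self):
        geno = [HOM_REF, HOM_ALT]
        gq = [40, 40]
        status = ["hom", "hom"]
        out = compare_variant(*self._arrays(geno, gq, status))
        assert out["c"] == 2

    def test_missing_and_unknown_skipped(self):
        geno = [MISSING, HET, HET]
        gq = [99, 40, 40]
        status = ["het", "unknown", "het"]
        out = compare_variant(*self._arrays(geno, gq, status))
        assert (out["n"], out["m"], out["c"]) == (1, 0, 1)

    def test_no_informative_animals_rejected(self):
        with pytest.raises(ValueError):
            compare_variant(*self._arrays([HET], [40], ["unknown"]))


class TestFilter:
    def _results(self):
        return pd.DataFrame(
            {
                "chrom": "1",
                "pos": [1, 2, 3],
                "id": ["a", "b", "c"],
                "ref": "A",
                "alt": "G",
                "vtype": "SNP",
                "n": [5, 20, 4],
                "m": [5, 20, 40],
                "c": [10, 36, 44],
                "fraction": [1.0, 0.89, 1.0],
                "p_c": [pc_exact(5, 5), pc_exact(20, 20), pc_exact(4, 40)],
            }
        )

    def test_three_criteria(self):
        out = concordance_filter(self._results(), n_poly=1000)
        assert out["concordant"].tolist() == [True, False, False]
        assert out.loc[1, "fail_reasons"] == "fraction"
        assert out.loc[2, "fail_reasons"] == "counts"

    def test_pc_5_5_passes_one_in_thousand(self):
        assert pc_exact(5, 5) < 1e-3

    def test_pc_threshold_strict(self):
        res = self._results().iloc[[0]].copy()
        n_poly = int(1 / res.loc[0, "p_c"])  # makes p_c == ~1/n_poly
        res.loc[0, "p_c"] = 1.0 / n_poly
        out = concordance_filter(res, n_poly=n_poly)
        assert not out.loc[0, "passes_pc"]

    def test_zero_n_poly_rejected(self):
        with pytest.raises(ValueError):
            concordance_filter(self._results(), n_poly=0)

    def test_monotone_in_thresholds(self):
        res = self._results()
        base = concordance_filter(res, n_poly=1000)["concordant"].sum()
        assert concordance_filter(res, n_poly=1000, fraction_min=0.95)["concordant"].sum() <= base
        assert concordance_filter(res, n_poly=1000, min_het=6)["concordant"].sum() <= base
        assert concordance_filter(res, n_poly=10**9)["concordant"].sum() <= base


class TestSweep:
    def test_counts_non_increasing(self):
        rng = np.random.default_rng(3)
        res = pd.DataFrame(
            {
                "n": rng.integers(5, 30, 50),
                "m": rng.integers(5, 30, 50),
            }
        )
        res["c"] = (res["n"] + res["m"] - rng.integers(0, 5, 50)).clip(lower=0)
        res["fraction"] = res["c"] / (res["n"] + res["m"])
        res["p_c"] = [pc_exact(int(a), int(b)) for a, b in zip(res["n"], res["m"])]
        sweep = sweep_tolerance(res, n_poly=500)
        counts = sweep["n_concordant"].to_numpy()
        assert np.all(np.diff(counts) <= 0)

    def test_empty_results_all_zero(self):
        res = pd.DataFrame({"n": [], "m": [], "c": [], "fraction": [], "p_c": []})
        sweep = sweep_tolerance(res, n_poly=10)
        assert (sweep["n_concordant"] == 0).all()


class TestAnnotateJoin:
    def _conc(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "pos": [10, 20, 30],
                "ref": ["A", "A", "A"],
                "alt": ["G", "G", "G"],
                "concordant": [True, True, True],
            }
        )

    def test_empty_annotation_all_unannotated(self):
        out = annotate_join(self._conc(), None)
        assert (out["consequence"] == "unannotated").all()

    def test_partial_annotation_counts(self):
        ann = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [10, 20],
                "ref": ["A", "A"],
                "alt": ["G", "G"],
                "consequence": ["intronic", "intronic"],
            }
        )
        out = annotate_join(self._conc(), ann)
        counts = out["consequence"].value_counts()
        assert counts["intronic"] == 2 and counts["unannotated"] == 1

    def test_duplicate_keys_first_wins(self):
        ann = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "pos": [10, 10],
                "ref": ["A", "A"],
                "alt": ["G", "G"],
                "consequence": ["intronic", "upstream"],
            }
        )
        with pytest.warns(UserWarning, match="duplicate"):
            out = annotate_join(self._conc(), ann)
        assert out.loc[out["pos"] == 10, "consequence"].iloc[0] == "intronic"


class TestConcordanceTable:
    def test_error_free_planted_variant_is_perfectly_concordant(self, small_pop):
        from concordqtl import simulate as sim

        cfg = small_pop.config
        pop = sim.simulate_population(
            sim.SimulationConfig(
                **{
                    **cfg.__dict__,
                    "genotype_error_rate": 0.0,
                    "gq_mean": 90.0,
                    "gq_sd": 1.0,
                }
            )
        )
        seq = sim.sequence_table(pop)
        calls = pop.truth[pop.truth.animal_id.isin(pop.sequenced_ids)][
            ["animal_id", "status"]
        ]
        table = concordance_table(seq, calls)
        row = table.iloc[cfg.qtl_variant_index]
        assert row["fraction"] == 1.0
        assert row["n"] + row["m"] == cfg.n_sequenced
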