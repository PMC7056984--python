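"""Dosage-compensation ratios and expression breadth."""

import numpy as np
import pandas as pd
import pytest

from fasterx.dosage import (
    chrom_median_expression,
    dosage_ratios,
    expression_breadth,
    summarize_breadth,
    unbiased_direction_fraction,
)
from fasterx.expression import TISSUES


def random_table(rng, n=400, n_auto=9):
    genes = [f"g{i}" for i in range(n)]
    chrom = pd.Series(
        rng.choice(["X"] + [f"LG{i}" for i in range(2, 2 + n_auto)], size=n),
        index=genes,
    )
    avgs = pd.DataFrame(
        rng.lognormal(2, 1, size=(n, 4)), index=genes, columns=list(TISSUES)
    )
    return avgs, chrom


class TestChromMedians:
    def test_matches_brute_force_groupby(self, rng):
        avgs, chrom = random_table(rng)
        got = chrom_median_expression(avgs, chrom, "TS")
        for c in got.index:
            manual = np.median(
                [avgs.loc[g, "TS"] for g in avgs.index if chrom[g] == c]
            )
            assert got[c] == pytest.approx(manual)

    def test_halved_x_construction(self, rng):
        avgs, chrom = random_table(rng, n=2000)
        avgs = avgs.copy()
        base = avgs["TS"].copy()
        avgs.loc[chrom == "X", "TS"] = 10.0
        avgs.loc[chrom != "X", "TS"] = 20.0
        med = chrom_median_expression(avgs, chrom, "TS")
        assert med["X"] == pytest.approx(med["LG2"] / 2)

    def test_unmapped_excluded(self, rng):
        avgs, chrom = random_table(rng, n=50)
        chrom.iloc[:10] = "unmapped"
        med = chrom_median_expression(avgs, chrom, "OV")
        assert "unmapped" not in med.index


class TestDosageRatios:
    def test_identical_distributions_all_ratios_one(self, rng):
        avgs, chrom = random_table(rng, n=3000)
        avgs = pd.DataFrame(
            np.tile(avgs[["TS"]].to_numpy(), (1, 4)), index=avgs.index,
            columns=list(TISSUES),
        )
        rep = dosage_ratios(avgs, chrom)
        for name in ("X_Ts/X_Ov", "A_Ts/A_Ov", "X_GTM/X_GTF", "A_GTM/A_GTF"):
            assert rep.ratios[name] == pytest.approx(1.0)
        assert rep.ratios["X_Ts/A_Ts"] == pytest.approx(1.0, abs=0.15)

    def test_global_rescale_invariance(self, rng):
        avgs, chrom = random_table(rng)
        r1 = dosage_ratios(avgs, chrom).ratios
        r2 = dosage_ratios(avgs * 37.5, chrom).ratios
        for k in r1:
            assert r1[k] == pytest.approx(r2[k])

    def test_median_of_medians_equals_single_autosome_when_identical(self):
        genes = [f"g{i}" for i in range(100)]
        chrom = pd.Series(
            ["X"] * 10 + [f"LG{2 + i % 9}" for i in range(90)], index=genes
        )
        avgs = pd.DataFrame(5.0, index=genes, columns=list(TISSUES))
        avgs.iloc[:10] = 2.0  # X genes
        rep = dosage_ratios(avgs, chrom, aggregation="median_of_medians")
        assert rep.ratios["X_Ts/A_Ts"] == pytest.approx(2.0 / 5.0)

    def test_pooled_aggregation_option(self, rng):
        avgs, chrom = random_table(rng)
        rep = dosage_ratios(avgs, chrom, aggregation="pooled_genes")
        a_pool = avgs.loc[chrom != "X", "TS"].median()
        assert rep.ratios["X_Ts/A_Ts"] == pytest.approx(
            avgs.loc[chrom == "X", "TS"].median() / a_pool
        )

    def test_missing_tissue_rejected(self, rng):
        avgs, chrom = random_table(rng)
        with pytest.raises(ValueError, match="GTF"):
            dosage_ratios(avgs.drop(columns="GTF"), chrom)


class TestBreadth:
    def test_boundaries_and_monotonicity(self):
        avgs = pd.DataFrame(
            [[5.0, 5.0, 5.0, 5.0], [1.0, 5.0, 5.0, 5.0], [0.5, 0.5, 0.5, 2.0]],
            index=["broad", "edge", "narrow"], columns=list(TISSUES),
        )
        b = expression_breadth(avgs)
        assert b["broad"] == 4
        assert b["edge"] == 3  # exactly 1.0 is not strictly greater
        assert b["narrow"] == 1
        for thr in (0.2, 1.0, 3.0):
            assert (expression_breadth(avgs, thr)
                    >= expression_breadth(avgs, thr + 1.0)).all()

    def test_class_summary_fractions(self):
        avgs = pd.DataFrame(
            [[5, 5, 5, 5], [5, 0.2, 5, 5], [9, 9, 9, 9]],
            index=["g1", "g2", "g3"], columns=list(TISSUES), dtype=float,
        )
        calls = pd.DataFrame(
            {"gonad_class": ["testis-biased", "testis-biased", "ovary-biased"]},
            index=avgs.index,
        )
        out = {s.label: s for s in summarize_breadth(expression_breadth(avgs),
                                                     calls)}
        assert out["testis-biased"].fraction_all_tissues == pytest.approx(0.5)
        assert out["ovary-biased"].fraction_all_tissues == pytest.approx(1.0)


class TestUnbiasedDirection:
    def test_fixture_with_22_of_190_male_higher(self, rng):
        genes = [f"g{i}" for i in range(190)]
        ts = np.full(190, 1.0)
        ov = np.full(190, 2.0)
        ts[:22] = 3.0  # exactly 22 male-higher
        avgs = pd.DataFrame(
            {"TS": ts, "OV": ov, "GTM": 1.0, "GTF": 1.0}, index=genes
        )
        chrom = pd.Series("X", index=genes)
        calls = pd.DataFrame({"gonad_class": "unbiased"}, index=genes)
        n_male, n_tot, p = unbiased_direction_fraction(avgs, calls, chrom)
        assert (n_male, n_tot) == (22, 190)
        assert p < 1e-5

    def test_balanced_split_p_near_one(self):
        genes = [f"g{i}" for i in range(100)]
        ts = np.r_[np.full(50, 3.0), np.full(50, 1.0)]
        avgs = pd.DataFrame({"TS": ts, "OV": 2.0, "GTM": 1.0, "GTF": 1.0},
                            index=genes)
        chrom = pd.Series("X", index=genes)
        calls = pd.DataFrame({"gonad_class": "unbiased"}, index=genes)
        _, _, p = unbiased_direction_fraction(avgs, calls, chrom)
        assert p > 0.9
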