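"""CDS validity filtering and reciprocal-best-hit identification."""

import numpy as np
import pytest

from fasterx.orthology import (
    CdsRecord,
    SearchHit,
    best_hit_per_query,
    check_cds,
    collapse_hsps,
    filter_valid_cds,
    longest_valid_per_gene,
    reciprocal_best_hits,
)

from .oracles import brute_force_rbh

NONSTOP_33 = "ATG" + "TTT" * 32  # exactly 33 codons, no stop


class TestCdsValidity:
    @pytest.mark.parametrize(
        "seq,valid,reason",
        [
            (NONSTOP_33, True, ""),
            (NONSTOP_33 + "TAA", True, ""),  # terminal stop allowed
            ("ATG" + "TTT" * 31, False, "shorter"),  # 32 aa
            ("ATGAANTTT" + "TTT" * 31, False, "ambiguous"),
            ("ATGTAA" + "TTT" * 32, False, "internal stop"),
            ("TTG" + "TTT" * 32, False, "start codon"),
            ("ATG" + "TTT" * 32 + "TT", False, "codon multiple"),
            ("", False, "empty"),
        ],
    )
    def test_rules(self, seq, valid, reason):
        ok, why = check_cds(seq)
        assert ok is valid
        assert reason in why

    def test_filter_sets_status_in_place(self):
        recs = [
            CdsRecord("g1", NONSTOP_33),
            CdsRecord("g2", "ATGNNN"),
        ]
        filter_valid_cds(recs)
        assert recs[0].valid and not recs[1].valid
        assert recs[1].reason

    def test_longest_valid_per_gene(self):
        recs = filter_valid_cds(
            [
                CdsRecord("g1", NONSTOP_33),
                CdsRecord("g1", "ATG" + "TTT" * 40),
                CdsRecord("g1", "ATGNNN" + "TTT" * 60),  # longer but invalid
                CdsRecord("g2", NONSTOP_33),
            ]
        )
        best = longest_valid_per_gene(recs)
        assert [r.gene_id for r in best] == ["g1", "g2"]
        assert len(best[0].sequence) == 3 * 41


class TestBestHit:
    def test_lower_evalue_wins(self):
        hits = [SearchHit("q1", "s1", 1e-50, 100), SearchHit("q1", "s2", 1e-10, 900)]
        assert best_hit_per_query(hits)["q1"].subject == "s1"

    def test_evalue_tie_broken_by_bitscore(self):
        hits = [SearchHit("q1", "s1", 1e-20, 200), SearchHit("q1", "s2", 1e-20, 180)]
        assert best_hit_per_query(hits)["q1"].subject == "s1"

    def test_full_tie_resolved_lexicographically_and_logged(self, caplog):
        hits = [SearchHit("q1", "sB", 1e-20, 200), SearchHit("q1", "sA", 1e-20, 200)]
        with caplog.at_level("WARNING"):
            assert best_hit_per_query(hits)["q1"].subject == "sA"
        assert any("tie" in r.message for r in caplog.records)

    def test_empty_and_negative(self):
        assert best_hit_per_query([]) == {}
        with pytest.raises(ValueError, match="negative"):
            best_hit_per_query([SearchHit("q", "s", -1.0, 5)])

    def test_hsp_collapse_keeps_best_row(self):
        hits = [SearchHit("q", "s", 1e-5, 50), SearchHit("q", "s", 1e-9, 40)]
        (kept,) = collapse_hsps(hits)
        assert kept.evalue == 1e-9


class TestReciprocalBestHits:
    def test_reciprocity_violation_excluded(self):
        fwd = [SearchHit("a", "b", 1e-30, 100)]
        rev = [SearchHit("b", "c", 1e-40, 120), SearchHit("b", "a", 1e-20, 90)]
        assert reciprocal_best_hits(fwd, rev) == []

    def test_evalue_ceiling_applies_to_both_directions(self):
        fwd = [SearchHit("a", "b", 1e-30, 100)]
        rev = [SearchHit("b", "a", 1e-3, 90)]
        assert reciprocal_best_hits(fwd, rev) == []
        assert len(reciprocal_best_hits(fwd, rev, evalue_max=1e-2)) == 1

    def test_matches_brute_force_oracle_on_noisy_fixture(self, rng):
        genes_a = [f"a{i}" for i in range(100)]
        genes_b = [f"b{i}" for i in range(100)]
        fwd, rev = [], []
        for i, (ga, gb) in enumerate(zip(genes_a, genes_b)):
            e = float(10.0 ** -rng.integers(7, 60))
            fwd.append(SearchHit(ga, gb, e, float(rng.integers(100, 500))))
            rev.append(SearchHit(gb, ga, e, float(rng.integers(100, 500))))
            # decoys: some tied on e-value with lower bit score, some weaker
            for _ in range(rng.integers(0, 3)):
                other = f"b{rng.integers(0, 100)}"
                if rng.random() < 0.5:
                    fwd.append(SearchHit(ga, other, e, 50.0))
                else:
                    fwd.append(
                        SearchHit(ga, other, e * 10.0,
                                  float(rng.integers(50, 600)))
                    )
            if rng.random() < 0.2:  # occasionally break reciprocity
                rev.append(SearchHit(gb, f"a{rng.integers(0, 100)}", e / 10.0,
                                     999.0))
        got = [(p.gene_a, p.gene_b) for p in reciprocal_best_hits(fwd, rev)]
        assert got == brute_force_rbh(fwd, rev)

    def test_symmetry_under_role_swap(self, rng):
        fwd = [SearchHit(f"a{i}", f"b{i}", 1e-20, 100.0) for i in range(20)]
        rev = [SearchHit(f"b{i}", f"a{i}", 1e-25, 110.0) for i in range(20)]
        direct = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(fwd, rev)}
        swapped = {(p.gene_b, p.gene_a) for p in reciprocal_best_hits(rev, fwd)}
        assert direct == swapped

    def test_pair_count_bounded_and_unique(self, rng):
        fwd = [SearchHit(f"a{i}", f"b{i % 5}", 1e-20, 100.0) for i in range(30)]
        rev = [SearchHit(f"b{i}", f"a{i}", 1e-20, 100.0) for i in range(5)]
        pairs = reciprocal_best_hits(fwd, rev)
        assert len(pairs) <= 5
        assert len({p.gene_a for p in pairs}) == len(pairs)
        assert len({p.gene_b for p in pairs}) == len(pairs)
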