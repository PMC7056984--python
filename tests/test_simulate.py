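"""Synthetic-data generator: codon pairs, expression matrices, fixtures."""

import numpy as np
import pandas as pd
import pytest

from fasterx.codons import STOP_CODONS, translate
from fasterx.orthology import read_blast6, reciprocal_best_hits
from fasterx.simulate import (
    CodonSimParams,
    ExprSimParams,
    FixtureParams,
    emit_fixture_bundle,
    simulate_codon_pair,
    simulate_expression,
)


class TestCodonSimulation:
    def test_zero_branch_length_keeps_descendants_identical(self):
        anc, a, b, _ = simulate_codon_pair(
            CodonSimParams(n_codons=50, branch_length=0.0, seed=1)
        )
        assert anc == a == b

    def test_omega_zero_forbids_amino_acid_change(self):
        anc, a, b, _ = simulate_codon_pair(
            CodonSimParams(n_codons=200, omega=0.0, branch_length=0.6, seed=2)
        )
        assert translate(anc) == translate(a) == translate(b)
        assert anc != a  # synonymous changes still accumulate

    def test_no_stop_codons_emitted(self):
        _, a, b, _ = simulate_codon_pair(
            CodonSimParams(n_codons=500, omega=1.5, branch_length=1.0, seed=3)
        )
        for seq in (a, b):
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not codons & STOP_CODONS

    def test_deterministic_given_seed(self):
        p = CodonSimParams(n_codons=100, seed=7)
        assert simulate_codon_pair(p) == simulate_codon_pair(p)
        p2 = CodonSimParams(n_codons=100, seed=8)
        assert simulate_codon_pair(p)[1] != simulate_codon_pair(p2)[1]

    def test_invalid_frequency_vector_rejected(self):
        bad = np.full(61, 1.0 / 61)
        bad[0] += 0.1
        with pytest.raises(ValueError, match="probability"):
            simulate_codon_pair(CodonSimParams(codon_frequencies=bad))


class TestExpressionSimulation:
    def test_truth_partitions_genes(self):
        counts, truth = simulate_expression(ExprSimParams(n_genes=300, seed=5))
        assert set(truth["gonad_class"]) <= {
            "ovary-biased", "testis-biased", "unbiased"
        }
        assert set(truth["gt_class"]) <= {
            "GT-female-biased", "GT-male-biased", "unbiased"
        }
        assert len(truth) == 300 and counts.shape == (300, 8)
        assert (counts.to_numpy() >= 0).all()

    def test_planted_fold_change_in_true_means(self):
        _, truth = simulate_expression(
            ExprSimParams(n_genes=400, fold_change=8.0, seed=6)
        )
        ov = truth[truth["gonad_class"] == "ovary-biased"]
        np.testing.assert_allclose(
            ov["true_mean_OV"] / ov["true_mean_TS"], 8.0
        )

    def test_dosage_factor_scales_male_tissues_of_x_genes(self):
        _, truth = simulate_expression(
            ExprSimParams(n_genes=400, fold_change=1.0,
                          male_X_dosage_factor=0.4, seed=6)
        )
        x = truth[truth["chromosome"] == "X"]
        np.testing.assert_allclose(x["true_mean_TS"] / x["true_mean_OV"], 0.4)
        a = truth[truth["chromosome"] != "X"]
        np.testing.assert_allclose(a["true_mean_TS"] / a["true_mean_OV"], 1.0)

    def test_homogeneous_limit_gives_equal_chromosome_medians(self):
        counts, truth = simulate_expression(
            ExprSimParams(n_genes=4000, fold_change=1.0, nb_dispersion=1e-4,
                          sd_log_expression=0.0, mean_log_expression=6.0,
                          seed=7)
        )
        med = counts.mean(axis=1).groupby(truth["chromosome"]).median()
        assert med.max() / med.min() == pytest.approx(1.0, rel=0.05)

    def test_single_replicate_warns(self):
        with pytest.warns(UserWarning, match="replicates"):
            ExprSimParams(n_genes=10, n_replicates=1).validate()

    def test_dosage_factor_recovered_by_pipeline_medians(self):
        # Monte-Carlo over seeds: with no planted bias, X_Ts/A_Ts tracks the
        # dosage factor
        from fasterx.dosage import dosage_ratios
        from fasterx.expression import average_replicates, fpkm_matrix

        ratios = []
        for seed in range(20):
            counts, truth = simulate_expression(
                ExprSimParams(n_genes=2000, fold_change=1.0,
                              male_X_dosage_factor=0.4, seed=seed)
            )
            avgs = average_replicates(
                fpkm_matrix(counts, pd.Series(1000, index=counts.index))
            )
            rep = dosage_ratios(avgs, truth["chromosome"])
            ratios.append(rep.ratios["X_Ts/A_Ts"])
        assert np.mean(ratios) == pytest.approx(0.4, abs=0.08)


class TestFixtureBundle:
    def test_same_seed_byte_identical(self, tmp_path):
        args = (
            CodonSimParams(n_codons=60, seed=11),
            ExprSimParams(n_genes=20, seed=12),
        )
        p1 = emit_fixture_bundle(*args, tmp_path / "a")
        p2 = emit_fixture_bundle(*args, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_rbh_recovers_planted_pairs(self, fixture_bundle):
        pairs = reciprocal_best_hits(
            read_blast6(fixture_bundle["fwd_hits.tsv"]),
            read_blast6(fixture_bundle["rev_hits.tsv"]),
        )
        truth = pd.read_csv(fixture_bundle["truth.tsv"], sep="\t", index_col=0)
        assert {(p.gene_a, p.gene_b) for p in pairs} == {
            (g, f"{g}_b") for g in truth.index
        }

    def test_tied_evalue_decoys_lose_on_bitscore(self, tmp_path):
        paths = emit_fixture_bundle(
            CodonSimParams(n_codons=60, seed=21),
            ExprSimParams(n_genes=30, seed=22),
            tmp_path,
            FixtureParams(n_decoys=10, decoy_tied_evalue=True),
        )
        pairs = reciprocal_best_hits(
            read_blast6(paths["fwd_hits.tsv"]), read_blast6(paths["rev_hits.tsv"])
        )
        assert all(p.gene_b == f"{p.gene_a}_b" for p in pairs)
        assert len(pairs) == 30

    def test_empty_gene_set_yields_wellformed_files(self, tmp_path):
        paths = emit_fixture_bundle(
            CodonSimParams(n_codons=60, seed=1),
            ExprSimParams(n_genes=0, seed=1),
            tmp_path,
        )
        assert paths["species_a.fasta"].read_text() == ""
        truth = pd.read_csv(paths["truth.tsv"], sep="\t")
        assert len(truth) == 0
        assert read_blast6(paths["fwd_hits.tsv"]) == []
        assert reciprocal_best_hits([], []) == []
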