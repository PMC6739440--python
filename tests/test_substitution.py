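import math

import numpy as np
import pandas as pd
import pytest

from cubpipe.codon_alignment import SuperSequence
from cubpipe.genetic_code import translate_cds
from cubpipe.substitution_analysis import (aggregate_codon_matrix,
                                           build_substitution_tables,
                                           classify_codon_pairs,
                                           reciprocal_asymmetry_test,
                                           two_hit_excess, two_hit_summary,
                                           usage_deviation_test)
from ._oracles import oracle_two_cell_chi2


def super_of(species, codons):
    nt = "".join(codons)
    return SuperSequence(species=species, peptide=translate_cds(nt),
                         codons=nt, cog_boundaries={})


def pair_tables(codons_a, codons_b):
    return build_substitution_tables(super_of("a", codons_a),
                                     super_of("b", codons_b))


class TestMatrices:
    def test_amino_acid_cells(self):
        tables = pair_tables(["GCT", "GCT"], ["GCT", "TCT"])  # AA vs AS
        assert tables.aa_matrix.loc["A", "A"] == 1
        assert tables.aa_matrix.loc["A", "S"] == 1

    def test_identical_inputs_purely_diagonal(self):
        codons = ["ATG", "AAA", "GCG"]
        tables = pair_tables(codons, codons)
        off = tables.aa_matrix.to_numpy().sum() - np.trace(tables.aa_matrix)
        assert off == 0

    def test_swapping_inputs_transposes(self):
        a, b = ["GCG", "AAA", "TTT"], ["TCG", "AAG", "TAT"]
        fwd = pair_tables(a, b)
        rev = pair_tables(b, a)
        assert fwd.aa_matrix.equals(rev.aa_matrix.T)
        assert fwd.codon_matrix.equals(rev.codon_matrix.T)

    def test_codon_cells(self):
        tables = pair_tables(["GCG", "GCG"], ["GCG", "TCG"])
        assert tables.codon_matrix.loc["GCG", "GCG"] == 1
        assert tables.codon_matrix.loc["GCG", "TCG"] == 1

    def test_cell_totals_and_aggregation_on_simulated_pair(self, small_sim, code):
        from cubpipe import codon_alignment as ca
        alns = []
        for cog_id, rows in small_sim.alignments.items():
            cds = {sp: small_sim.cds[sp][gene] for sp, gene, _ in rows}
            aln = ca.back_translate_alignment(
                cog_id, [(sp, row) for sp, _, row in rows], cds, code)
            alns.append(ca.remove_gapped_columns(aln))
        retained, _ = ca.filter_short_cogs(alns)
        supers = ca.concatenate_superseqs(retained, code)
        sp1, sp2 = small_sim.species[0], small_sim.species[-1]
        tables = build_substitution_tables(supers[sp1], supers[sp2], code)
        assert tables.aa_matrix.to_numpy().sum() == tables.n_positions
        assert tables.codon_matrix.to_numpy().sum() == tables.n_positions
        assert aggregate_codon_matrix(tables.codon_matrix, code).equals(
            tables.aa_matrix)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            pair_tables(["AAA"], ["AAA", "AAA"])


class TestUsageDeviation:
    def test_hand_example_30_10(self):
        # 30 vs 10 -> e = 20, chi2 = 100/20 + 100/20 = 10
        tables = pair_tables(["AAA"] * 30 + ["GGG"] * 10,
                             ["AAA"] * 10 + ["GGG"] * 30)
        result = usage_deviation_test(tables)
        assert result.loc["K", "chi2"] == pytest.approx(10.0)
        assert result.loc["G", "chi2"] == pytest.approx(10.0)

    def test_equal_counts_null(self):
        tables = pair_tables(["AAA"] * 8, ["AAA"] * 8)
        result = usage_deviation_test(tables)
        assert result.loc["K", "chi2"] == 0.0
        assert result.loc["K", "pvalue"] == pytest.approx(1.0)

    def test_oracle_agreement_on_random_counts(self, rng):
        for _ in range(100):
            c1, c2 = int(rng.integers(5, 500)), int(rng.integers(5, 500))
            from cubpipe.substitution_analysis import _chi2_two_cell
            chi2, p, _ = _chi2_two_cell(c1, c2)
            ref_chi2, ref_p = oracle_two_cell_chi2(c1, c2)
            assert chi2 == pytest.approx(ref_chi2, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)

    def test_type_one_error_near_nominal(self, rng):
        # symmetric usage: rejection rate of the raw test ~ alpha
        rejections = 0
        reps = 400
        for _ in range(reps):
            c1, c2 = rng.poisson(100, size=2)
            from cubpipe.substitution_analysis import _chi2_two_cell
            _, p, _ = _chi2_two_cell(int(c1), int(c2))
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.09


class TestReciprocalAsymmetry:
    def test_printed_ala_ser_counts(self):
        # 263 Ala->Ser vs 169 Ser->Ala: e = 216, chi2 = 2 * 47^2 / 216
        codons_a = ["GCT"] * 263 + ["TCT"] * 169
        codons_b = ["TCT"] * 263 + ["GCT"] * 169
        result = reciprocal_asymmetry_test(pair_tables(codons_a, codons_b))
        row = result[(result["aa_1"] == "A") & (result["aa_2"] == "S")].iloc[0]
        assert row["chi2"] == pytest.approx(2 * 47**2 / 216, abs=1e-10)
        assert row["chi2"] == pytest.approx(20.4537, abs=1e-3)
        assert row["pvalue"] < 1e-4

    def test_balanced_counts_give_zero(self):
        codons_a = ["GCT"] * 5 + ["TCT"] * 5
        codons_b = ["TCT"] * 5 + ["GCT"] * 5
        result = reciprocal_asymmetry_test(pair_tables(codons_a, codons_b))
        assert result.iloc[0]["chi2"] == 0.0

    def test_low_expected_flagged_not_tested(self):
        codons_a = ["GCT"] * 3 + ["TCT"] * 2
        codons_b = ["TCT"] * 3 + ["GCT"] * 2
        result = reciprocal_asymmetry_test(pair_tables(codons_a, codons_b))
        row = result.iloc[0]
        assert bool(row["low_count"])
        assert math.isnan(row["pvalue"])


class TestClassification:
    def test_status_assignment(self):
        frame = classify_codon_pairs(
            super_of("a", ["GCG", "GCG", "GCG"]),
            super_of("b", ["GCG", "GCA", "TCA"]))
        row = frame.loc["GCG"]
        assert (row["conserved"], row["synonymous"], row["nonsynonymous"]) == (1, 1, 1)
        assert (row["nt0"], row["nt1"], row["nt2"]) == (1, 1, 1)

    def test_identical_sequences_all_conserved(self):
        codons = ["ATG", "AAA", "GGG"]
        frame = classify_codon_pairs(super_of("a", codons), super_of("b", codons))
        assert frame["conserved"].sum() == 3
        assert frame["synonymous"].sum() == 0
        assert frame["nonsynonymous"].sum() == 0


class TestTwoHit:
    def fig9_like_tables(self):
        """49 positions: Ala GCG in species a vs Ser codons in species b."""
        targets = ["TCG"] * 6 + ["TCA"] * 23 + ["TCT"] * 15 + ["AGT"] * 5
        return pair_tables(["GCG"] * 49, targets)

    def test_planted_counts_reproduce_fractions(self):
        summary = two_hit_summary(self.fig9_like_tables())
        row = summary[(summary["aa_from"] == "A") &
                      (summary["aa_to"] == "S") &
                      (summary["source_codon"] == "GCG")].iloc[0]
        assert row["n_total"] == 49
        assert row["n_single"] == 6          # only GCG->TCG is one step
        assert row["n_single"] / row["n_total"] == pytest.approx(6 / 49)
        assert row["obs_multi_frac"] >= 38 / 49
        assert row["baseline_multi_frac"] == 0.0
        assert row["excess"] == pytest.approx(43 / 49)

    def test_single_step_only_target_gives_zero_multi(self):
        # Trp TGG -> Cys family: TGT/TGC, both 1 step away
        summary = two_hit_summary(pair_tables(["TGG"] * 4,
                                              ["TGT", "TGT", "TGC", "TGC"]))
        row = summary.iloc[0]
        assert row["obs_multi_frac"] == 0.0
        assert row["excess"] == 0.0

    def test_multi_only_reachable_family_has_zero_excess(self):
        # Lys AAA -> Asp family is >= 2 steps from AAA: baseline = observed
        summary = two_hit_summary(pair_tables(["AAA"] * 3,
                                              ["GAT", "GAC", "GAT"]))
        row = summary.iloc[0]
        assert row["baseline_multi_frac"] == 1.0
        assert row["excess"] == 0.0

    def test_weighted_excess_aggregation(self):
        summary = two_hit_summary(self.fig9_like_tables())
        assert two_hit_excess(summary) == pytest.approx(43 / 49)
        assert math.isnan(two_hit_excess(summary.iloc[0:0]))
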