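import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cubpipe.composition import (codon_counts, codon_gc3_correlations,
                                 composition_table, enc, enc_expected_curve,
                                 gc_by_position, neutrality_regression, rscu)
from ._oracles import (oracle_enc, oracle_gc_by_position, oracle_rscu)
from .conftest import random_counts


def counts_from(code, mapping):
    series = pd.Series(0, index=list(code.sense_codons), dtype=int)
    for codon, n in mapping.items():
        series[codon] = n
    return series


class TestCodonCounts:
    def test_simple(self, code):
        counts = codon_counts("ATGATG", code)
        assert counts["ATG"] == 2
        assert counts.sum() == 2

    def test_total_conserved(self, code):
        counts = codon_counts("ATGAAACCCGGG", code)
        assert counts.sum() == 4

    def test_stop_codon_rejected(self, code):
        with pytest.raises(ValueError):
            codon_counts("ATGTAA", code)


class TestGCByPosition:
    def test_hand_example(self, code):
        counts = codon_counts("ATGGCGTTA", code)  # third positions G, G, A
        gc = gc_by_position(counts, code)
        assert gc.gc3 == pytest.approx(2 / 3)

    def test_saturation(self, code):
        gc = gc_by_position(codon_counts("GCGGCG", code), code)
        assert (gc.gc1, gc.gc2, gc.gc3) == (1.0, 1.0, 1.0)

    def test_gc12_is_mean(self, code):
        counts = counts_from(code, {"ACT": 1, "GTT": 1})  # gc1=0.5, gc2=0.5
        gc = gc_by_position(counts, code)
        assert gc.gc12 == pytest.approx((gc.gc1 + gc.gc2) / 2)

    def test_counts_and_string_agree(self, code, rng):
        counts = random_counts(rng, code)
        seq = "".join(c * int(n) for c, n in counts.items())
        assert gc_by_position(codon_counts(seq, code), code) == \
            gc_by_position(counts, code)

    def test_synonymous_only_variant_excludes_met_trp(self, code):
        counts = counts_from(code, {"ATG": 10, "AAA": 10})
        gc3s = gc_by_position(counts, code, synonymous_only=True).gc3
        assert gc3s == 0.0  # ATG's forced G excluded
        assert gc_by_position(counts, code).gc3 == 0.5


class TestRSCU:
    def test_two_fold_example(self, code):
        values = rscu(counts_from(code, {"AAA": 3, "AAG": 1}), code)
        assert values["AAA"] == pytest.approx(1.5)
        assert values["AAG"] == pytest.approx(0.5)

    def test_monopolised_family(self, code):
        values = rscu(counts_from(code, {"TTT": 4}), code)
        assert values["TTT"] == pytest.approx(2.0)
        assert values["TTC"] == pytest.approx(0.0)

    def test_uniform_usage_gives_ones(self, code):
        counts = pd.Series(5, index=list(code.sense_codons))
        values = rscu(counts, code)
        assert np.allclose(values, 1.0)

    def test_unobserved_family_missing_not_zero(self, code):
        values = rscu(counts_from(code, {"AAA": 2}), code)
        assert math.isnan(values["GGG"])

    def test_met_trp_excluded(self, code):
        values = rscu(counts_from(code, {"ATG": 5, "TGG": 5}), code)
        assert "ATG" not in values.index and "TGG" not in values.index
        assert len(values) == 59

    @settings(derandomize=True, max_examples=60)
    @given(data=st.data())
    def test_family_normalisation_property(self, code, data):
        # within any observed family, RSCU sums to the family size
        mapping = {}
        for aa, fam in code.families.items():
            if len(fam) == 1:
                continue
            for c in fam:
                mapping[c] = data.draw(st.integers(0, 30), label=c)
        values = rscu(counts_from(code, mapping), code)
        for aa, fam in code.families.items():
            if len(fam) == 1:
                continue
            total = sum(mapping[c] for c in fam)
            if total == 0:
                assert values[list(fam)].isna().all()
            else:
                assert values[list(fam)].sum() == pytest.approx(len(fam))
                assert (values[list(fam)] >= 0).all()

    def test_family_sums_and_oracle_agreement(self, code, rng):
        for _ in range(100):
            counts = random_counts(rng, code)
            mine = rscu(counts, code)
            ref = oracle_rscu(counts.to_dict(), code.families)
            for codon, expected in ref.items():
                got = mine[codon]
                assert (math.isnan(got) and math.isnan(expected)) or \
                    got == pytest.approx(expected, abs=1e-12)
            for aa, family in code.families.items():
                if len(family) == 1:
                    continue
                total = sum(counts[c] for c in family)
                if total > 0:
                    assert mine[list(family)].sum() == pytest.approx(len(family))


class TestENC:
    def test_single_codon_per_amino_acid_is_20(self, code):
        chosen = {fam[0]: 10 for fam in code.families.values()}
        assert enc(counts_from(code, chosen), code) == pytest.approx(20.0)

    def test_uniform_61_codons_capped_at_61(self, code):
        counts = pd.Series(100, index=list(code.sense_codons))
        assert enc(counts, code) == pytest.approx(61.0)

    def test_range_and_oracle_on_random_inputs(self, code, rng):
        for _ in range(100):
            counts = random_counts(rng, code)
            mine = enc(counts, code)
            ref = oracle_enc(counts.to_dict(), code.families)
            if math.isnan(ref):
                assert math.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-10)
                assert 20.0 <= mine <= 61.0

    def test_converges_under_count_scaling(self, code, rng):
        # scaling counts leaves within-family proportions fixed, so ENC must
        # approach the analytic limit with F = sum p^2 as counts grow
        base = random_counts(rng, code, max_codons=400)
        limit_f: dict[int, list[float]] = {}
        for aa, fam in code.families.items():
            if len(fam) == 1:
                continue
            n = sum(base[c] for c in fam)
            if n == 0:
                continue
            limit_f.setdefault(len(fam), []).append(
                sum((base[c] / n) ** 2 for c in fam))
        fbar = {k: np.mean(v) for k, v in limit_f.items()}
        if 3 not in fbar:
            fbar[3] = (fbar[2] + fbar[4]) / 2
        limit = min(61.0, max(20.0, 2 + sum(
            {2: 9, 3: 1, 4: 5, 6: 3}[k] / fbar[k] for k in (2, 3, 4, 6))))
        d10 = abs(enc(base * 10, code) - limit)
        d1000 = abs(enc(base * 1000, code) - limit)
        assert d1000 <= 0.05
        assert d1000 <= d10 + 1e-9

    def test_f3_imputation_used_when_ile_absent(self, code):
        chosen = {fam[0]: 10 for aa, fam in code.families.items() if aa != "I"}
        value = enc(counts_from(code, chosen), code)
        assert value == pytest.approx(20.0)


class TestENCExpectedCurve:
    def test_midpoint(self):
        assert enc_expected_curve(0.5) == pytest.approx(60.5)

    def test_at_zero(self):
        assert enc_expected_curve(0.0) == pytest.approx(31.0)

    def test_nonlinear_term_symmetric(self):
        for s in (0.1, 0.25, 0.4):
            left = enc_expected_curve(s) - s
            right = enc_expected_curve(1 - s) - (1 - s)
            assert left == pytest.approx(right)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            enc_expected_curve(1.5)


class TestNeutralityRegression:
    def test_flat_gc12_slope_zero(self):
        fit = neutrality_regression([0.2, 0.5, 0.8], [0.45, 0.45, 0.45])
        assert fit.slope == pytest.approx(0.0)

    def test_perfect_neutrality(self):
        fit = neutrality_regression([0.2, 0.5, 0.8], [0.2, 0.5, 0.8])
        assert fit.slope == pytest.approx(1.0)
        assert fit.r == pytest.approx(1.0)

    def test_degenerate_variance_flagged(self):
        fit = neutrality_regression([0.4, 0.4, 0.4], [0.1, 0.2, 0.3])
        assert math.isnan(fit.slope)
        assert fit.note == "zero GC3 variance"

    def test_selection_regime_slope_near_zero(self, rng):
        # GC3 spread wide, GC12 pinned near 0.45: slope must be ~0
        gc3 = rng.uniform(0.1, 0.9, size=200)
        gc12 = 0.45 + rng.normal(0, 0.01, size=200)
        fit = neutrality_regression(gc3, gc12)
        assert abs(fit.slope) < 0.05


class TestCodonGC3Correlations:
    @staticmethod
    def _genes_with_gradient(code, rng, n=40):
        genes = []
        for i in range(n):
            tilt = 0.1 + 0.8 * i / (n - 1)
            codons = []
            for aa, fam in code.families.items():
                gc_ended = [c for c in fam if c[2] in "GC"]
                at_ended = [c for c in fam if c[2] not in "GC"]
                for _ in range(12):
                    if gc_ended and (not at_ended or rng.random() < tilt):
                        codons.append(gc_ended[int(rng.integers(len(gc_ended)))])
                    else:
                        codons.append(at_ended[int(rng.integers(len(at_ended)))])
            genes.append((f"g{i}", "".join(codons)))
        return genes

    def test_sign_pattern_follows_codon_ending(self, code, rng):
        table = composition_table(self._genes_with_gradient(code, rng), code)
        corr = codon_gc3_correlations(table, code)
        gc_ended = [c for c in corr.index if c[2] in "GC"]
        at_ended = [c for c in corr.index if c[2] not in "GC"]
        assert np.nanmean(corr[gc_ended]) > 0.3
        assert np.nanmean(corr[at_ended]) < -0.3

    def test_matches_direct_pearson(self, code, rng):
        from scipy.stats import pearsonr
        table = composition_table(self._genes_with_gradient(code, rng, n=20), code)
        corr = codon_gc3_correlations(table, code)
        col = "rscu_GCG"
        mask = table[col].notna()
        expected = pearsonr(table.loc[mask, "gc3"], table.loc[mask, col]).statistic
        assert corr["GCG"] == pytest.approx(expected, abs=1e-12)

    def test_constant_gc3_all_missing(self, code):
        genes = [(f"g{i}", "GCGGCAGCT" * 4) for i in range(5)]
        table = composition_table(genes, code)
        corr = codon_gc3_correlations(table, code)
        assert corr.isna().all()


class TestOracleGC:
    def test_gc_matches_bruteforce(self, code, rng):
        for _ in range(50):
            counts = random_counts(rng, code)
            codon_list = [c for c, n in counts.items() for _ in range(int(n))]
            gc = gc_by_position(counts, code)
            assert gc == pytest.approx(oracle_gc_by_position(codon_list),
                                       abs=1e-12)
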