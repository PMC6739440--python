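import numpy as np
import pandas as pd
import pytest

from cubpipe.clustering_expression import (ClusteringError, DEFAULT_GRID,
                                           StratificationError,
                                           codon_usage_pca, preferred_codons,
                                           rscu_cluster_consensus)
from cubpipe.composition import composition_table, counts_table
from cubpipe.seq_io import ExpressionTable
from cubpipe.synthetic_data import (SimulationConfig, simulate_expression,
                                    simulate_ortholog_set)


def species_rscu_from_sim(data, code):
    """Species-level RSCU vectors from pooled (concatenated) CDS."""
    units = []
    for sp in data.species:
        pooled = "".join(c.nucleotides for c in data.cds[sp].values())
        units.append((sp, pooled))
    table = composition_table(units, code)
    return table[[c for c in table.columns if c.startswith("rscu_")]]


class TestConsensusClustering:
    def test_split_follows_gc3_groups(self, code):
        data = simulate_ortholog_set(SimulationConfig(
            seed=3, n_species=6, n_cogs=30, protein_length_mean=120,
            gc3_targets=(0.3, 0.3, 0.3, 0.7, 0.7, 0.7)))
        consensus = rscu_cluster_consensus(species_rscu_from_sim(data, code))
        low = ("sp01", "sp02", "sp03")
        high = ("sp04", "sp05", "sp06")
        assert consensus.has_clade(low) or consensus.has_clade(high)
        assert consensus.support.get(frozenset(low), 1.0) == 1.0 or \
            consensus.support.get(frozenset(high), 1.0) == 1.0

    def test_identical_trees_give_full_support(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.random((5, 8)),
                             index=[f"s{i}" for i in range(5)])
        # distance is well separated, so all linkages agree
        frame.iloc[:2] += 10.0
        consensus = rscu_cluster_consensus(frame)
        assert all(v == 1.0 for v in consensus.support.values())
        assert consensus.has_clade(["s0", "s1"])

    def test_identical_vectors_are_siblings_everywhere(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.random((4, 6)),
                             index=["a", "b", "c", "d"])
        frame.loc["b"] = frame.loc["a"]
        consensus = rscu_cluster_consensus(frame)
        assert consensus.support[frozenset({"a", "b"})] == 1.0
        for newick in consensus.newicks.values():
            assert "a:0" in newick and "b:0" in newick

    def test_invariant_under_grid_permutation(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.random((6, 10)),
                             index=[f"s{i}" for i in range(6)])
        fwd = rscu_cluster_consensus(frame, DEFAULT_GRID)
        rev = rscu_cluster_consensus(frame, tuple(reversed(DEFAULT_GRID)))
        assert fwd.consensus_newick == rev.consensus_newick
        assert fwd.support == rev.support

    def test_missing_entries_rejected(self):
        frame = pd.DataFrame(np.ones((3, 4)), index=["a", "b", "c"])
        frame.iloc[0, 0] = np.nan
        with pytest.raises(ClusteringError, match="impute"):
            rscu_cluster_consensus(frame)


def _expression_for(genes, values):
    return ExpressionTable(species="sp", values=dict(zip(genes, values)))


class TestOrdination:
    @staticmethod
    def _sim_with_coupling(code, coupling):
        # high-expression genes re-tilted toward GC-ended codons
        gc_ended = tuple(sorted(
            c for c in code.sense_codons
            if c[2] in "GC" and len(code.families[code.translate(c)]) > 1))
        config = SimulationConfig(
            seed=9, n_species=1, n_cogs=120, protein_length_mean=300,
            gc3_targets=(0.5,), expression_coupling=coupling,
            preferred_set=gc_ended)
        data = simulate_ortholog_set(config)
        simulate_expression(data, config)
        sp = data.species[0]
        counts = counts_table(list(data.cds[sp].values()), code)
        return counts, data.expression[sp]

    def test_identical_genes_identical_coordinates(self, code):
        counts, expr = self._sim_with_coupling(code, 0.0)
        genes = list(counts.index)[:12]
        frame = counts.loc[genes].copy()
        frame.iloc[1] = frame.iloc[0]
        expr_sub = ExpressionTable("sp", {g: expr.values[g] for g in genes})
        result = codon_usage_pca(frame, expr_sub)
        xy = result.coords[["axis1", "axis2"]].to_numpy()
        assert np.allclose(xy[0], xy[1], atol=1e-12)

    def test_pca_is_centred(self, code):
        counts, expr = self._sim_with_coupling(code, 0.0)
        result = codon_usage_pca(counts, expr)
        xy = result.coords[["axis1", "axis2"]].to_numpy()
        assert np.allclose(xy.mean(axis=0), 0.0, atol=1e-9)

    @pytest.mark.parametrize("mode", ["pca", "coa"])
    def test_strata_separate_under_planted_bias(self, code, mode):
        counts, expr = self._sim_with_coupling(code, 0.5)
        result = codon_usage_pca(counts, expr, mode=mode)
        coords = result.coords
        hi = coords[coords["label"] == "high"]["axis1"]
        lo = coords[coords["label"] == "low"]["axis1"]
        gap = abs(hi.mean() - lo.mean())
        spread = (hi.std() + lo.std()) / 2
        assert gap > spread

    def test_all_equal_expression_rejected(self, code):
        counts, expr = self._sim_with_coupling(code, 0.0)
        flat = ExpressionTable("sp", {g: 1.0 for g in expr.values})
        with pytest.raises(StratificationError):
            codon_usage_pca(counts, flat)


class TestPreferredCodons:
    @staticmethod
    def _rscu_and_counts(data, code):
        sp = data.species[0]
        cds = list(data.cds[sp].values())
        table = composition_table(cds, code)
        rscu = table[[c for c in table.columns if c.startswith("rscu_")]]
        return rscu, counts_table(cds, code)

    def test_planted_enrichment_recovered(self, code):
        config = SimulationConfig(
            seed=21, n_species=1, n_cogs=200, protein_length_mean=300,
            gc3_targets=(0.5,), expression_coupling=0.27,
            preferred_set=("GCC",))
        data = simulate_ortholog_set(config)
        simulate_expression(data, config)
        rscu, _ = self._rscu_and_counts(data, code)
        calls = preferred_codons(rscu, data.expression[data.species[0]])
        assert bool(calls.loc["GCC", "preferred"])
        assert calls.loc["GCC", "mean_high"] > calls.loc["GCC", "mean_low"]

    def test_direction_rule_blocks_depleted_codons(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(80)]
        expr = _expression_for(genes, np.arange(80, dtype=float))
        base = rng.normal(1.0, 0.05, size=(80, 2))
        frame = pd.DataFrame(base, index=genes, columns=["AAA", "AAG"])
        hi = expr.values
        for g in genes:
            if hi[g] > 70:          # strongly depleted in high set
                frame.loc[g, "AAA"] -= 0.8
        calls = preferred_codons(frame, expr)
        row = calls.loc["AAA"]
        assert row["p_adj"] < 0.05 and row["mean_high"] < row["mean_low"]
        assert not row["preferred"]

    def test_invariant_under_monotone_expression_transform(self, code):
        config = SimulationConfig(
            seed=23, n_species=1, n_cogs=100, protein_length_mean=120,
            gc3_targets=(0.5,), expression_coupling=0.27)
        data = simulate_ortholog_set(config)
        simulate_expression(data, config)
        sp = data.species[0]
        rscu, _ = self._rscu_and_counts(data, code)
        expr = data.expression[sp]
        transformed = ExpressionTable(sp, {g: np.log1p(v) ** 2
                                           for g, v in expr.values.items()})
        a = preferred_codons(rscu, expr)
        b = preferred_codons(rscu, transformed)
        pd.testing.assert_series_equal(a["preferred"], b["preferred"])

    def test_chisq_mode_agrees_on_strong_signal(self, code):
        config = SimulationConfig(
            seed=25, n_species=1, n_cogs=200, protein_length_mean=300,
            gc3_targets=(0.5,), expression_coupling=0.4,
            preferred_set=("GCC",))
        data = simulate_ortholog_set(config)
        simulate_expression(data, config)
        rscu, counts = self._rscu_and_counts(data, code)
        calls = preferred_codons(rscu, data.expression[data.species[0]],
                                 method="chisq", gene_counts=counts)
        assert bool(calls.loc["GCC", "preferred"])
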