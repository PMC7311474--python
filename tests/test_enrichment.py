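"""Tetramer enrichment, GO filtering, USPS, shift tests, correlations."""
import numpy as np
import pandas as pd
import pytest

import oracles
from scapa.enrichment import (UspsSet, define_usps, enrichment_correlation,
                              geneset_shift, go_enrich,
                              per_gene_red_correlation,
                              red_expression_correlation, tetramer_enrichment,
                              tetramer_presence, to_rna)
from scapa.synthetic import simulate_sequences


def strip_motif(seq: str, motif: str = "TTTT") -> str:
    while motif in seq:
        seq = seq.replace(motif, "TTCA", 1)
    return seq


class TestTetramers:
    def test_presence_counts_match_naive_scan(self, rng):
        seqs = simulate_sequences(30, 120, seed=5)
        counts = tetramer_presence(seqs)
        for kmer in rng.choice(counts.index, size=40, replace=False):
            assert counts[kmer] == oracles.count_kmer_presence(seqs, kmer)

    def test_planted_motif_is_top_scoring(self):
        set_a = simulate_sequences(60, 100, seed=6, motif="TTTT",
                                   planted_fraction=1.0)
        set_b = [strip_motif(s) for s in simulate_sequences(60, 100, seed=7)]
        scores = tetramer_enrichment(set_a, set_b)["score"]
        assert scores.idxmax() == "TTTT"
        assert scores["TTTT"] > 5

    def test_identical_sets_all_zero(self):
        seqs = simulate_sequences(20, 80, seed=8)
        scores = tetramer_enrichment(seqs, list(seqs))["score"]
        assert (scores == 0).all()

    def test_swap_antisymmetry_exact(self):
        a = simulate_sequences(25, 90, seed=9, motif="GGGG",
                               planted_fraction=0.6)
        b = simulate_sequences(25, 90, seed=10)
        ab = tetramer_enrichment(a, b)["score"]
        ba = tetramer_enrichment(b, a)["score"]
        assert (ab == -ba).all()

    def test_occurrence_mode(self):
        a = ["TTTTTTTT"] * 5     # T-runs: every window is TTTT
        b = ["ACGTACGTAC"] * 5
        df = tetramer_enrichment(a, b, mode="occurrence")
        assert df.loc["TTTT", "score"] > 0
        assert df.loc["TTTT", "count_a_with"] == 5 * 5  # 5 windows per seq

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            tetramer_enrichment([], ["ACGT"])

    def test_rna_display(self):
        assert to_rna("TTTG") == "UUUG"


class TestEnrichmentCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = pd.Series(rng.normal(size=256),
                      index=tetramer_enrichment(["ACGTAAAA"], ["ACGTCCCC"]).index)
        assert enrichment_correlation(x, x) == pytest.approx(1.0)
        assert enrichment_correlation(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_nan(self, rng):
        x = pd.Series(rng.normal(size=10), index=range(10))
        y = pd.Series(1.0, index=range(10))
        assert np.isnan(enrichment_correlation(x, y))

    def test_shared_planted_signal_with_opposed_signs(self):
        """A motif enriched in set A of comparison X but depleted in set A
        of comparison Y produces negatively correlated score vectors."""
        motif_rich = simulate_sequences(50, 100, seed=12, motif="TTTT",
                                        planted_fraction=0.9, copies=2)
        plain = [strip_motif(s) for s in simulate_sequences(50, 100, seed=13)]
        x = tetramer_enrichment(motif_rich, plain)
        y = tetramer_enrichment(plain, motif_rich)
        assert enrichment_correlation(x, y) < -0.5


class TestGoEnrich:
    def test_hypergeometric_worked_example(self):
        universe = [f"g{i}" for i in range(20)]
        term_map = {"T1": set(universe[:5])}
        query = set(universe[1:5]) | {"g10"}  # overlap 4
        res = go_enrich(query, universe, term_map)
        expected = oracles.hypergeom_upper_tail(4, 20, 5, 5)
        assert res.loc["T1", "p_value"] == pytest.approx(expected, abs=1e-10)

    def test_generic_term_discarded(self):
        universe = [f"g{i}" for i in range(1200)]
        term_map = {"BIG": set(universe[:1001]), "OK": set(universe[:10])}
        res = go_enrich(set(universe[:5]), universe, term_map)
        assert "BIG" not in res.index
        assert "OK" in res.index

    def test_duplicate_term_discarded_by_redundancy(self):
        universe = [f"g{i}" for i in range(40)]
        strong = set(universe[:8])
        term_map = {"A": strong, "B": strong | {"g30"}}  # B larger, weaker
        res = go_enrich(strong, universe, term_map)
        assert bool(res.loc["A", "kept"]) is True
        assert bool(res.loc["B", "kept"]) is False

    def test_query_outside_universe_errors(self):
        with pytest.raises(ValueError):
            go_enrich({"x"}, {"a", "b"}, {"T": {"a"}})

    def test_order_stability(self, rng):
        universe = [f"g{i}" for i in range(60)]
        terms = {
            f"T{i}": set(rng.choice(universe, size=rng.integers(3, 20),
                                    replace=False))
            for i in range(15)
        }
        query = set(rng.choice(universe, size=12, replace=False))
        df1 = pd.DataFrame([{"term_id": t, "gene_id": g}
                            for t in terms for g in sorted(terms[t])])
        df2 = df1.sample(frac=1, random_state=1)
        assert go_enrich(query, universe, df1).equals(
            go_enrich(query, universe, df2))

    def test_filters_match_brute_force_oracle(self, rng):
        universe = [f"g{i}" for i in range(50)]
        for trial in range(30):
            terms = {
                f"T{i:02d}": set(rng.choice(universe,
                                            size=rng.integers(2, 25),
                                            replace=False))
                for i in range(rng.integers(3, 30))
            }
            query = set(rng.choice(universe, size=rng.integers(3, 20),
                                   replace=False))
            res = go_enrich(query, universe, terms)
            # p-values match exhaustive enumeration ...
            for term_id, row in res.iterrows():
                expected_p = oracles.hypergeom_upper_tail(
                    int(row["overlap"]), len(universe), int(row["n_genes"]),
                    len(query))
                assert row["p_value"] == pytest.approx(expected_p, abs=1e-10)
            # ... and the generic/redundancy filter logic matches the
            # oracle run on the same p-values (immune to float p ties)
            kept = list(res.index[res["kept"]])
            assert kept == oracles.go_filter(
                terms, query, set(universe),
                pvalues=res["p_value"].to_dict())


class TestUsps:
    def _de(self, up_genes, all_genes):
        return pd.DataFrame(
            {"call": ["up" if g in up_genes else "unchanged" for g in all_genes]},
            index=all_genes)

    def test_toy_definition(self):
        genes = [f"g{i}" for i in range(30)]
        common_up = set(genes[:10])
        term_map = {"SECRETION": set(genes[:4]), "OTHER": set(genes[20:25])}
        usps = define_usps(self._de(common_up, genes),
                           self._de(common_up, genes), term_map,
                           n_top_terms=1)
        assert usps.genes == frozenset(genes[:4])
        assert usps.top_terms == ("SECRETION",)

    def test_disjoint_up_sets_empty(self):
        genes = [f"g{i}" for i in range(20)]
        usps = define_usps(self._de(set(genes[:5]), genes),
                           self._de(set(genes[10:15]), genes),
                           {"T": set(genes[:8])})
        assert usps.genes == frozenset()
        assert usps.common_up == frozenset()

    def test_redundancy_filter_shapes_top_terms(self, rng):
        """USPS reflects the post-filter kept terms, as a brute-force
        combination of the GO oracle and set logic predicts."""
        genes = [f"g{i}" for i in range(40)]
        for trial in range(15):
            up_a = set(rng.choice(genes, size=15, replace=False))
            up_b = set(rng.choice(genes, size=15, replace=False))
            terms = {
                f"T{i}": set(rng.choice(genes, size=rng.integers(3, 15),
                                        replace=False))
                for i in range(10)
            }
            usps = define_usps(self._de(up_a, genes), self._de(up_b, genes),
                               terms, n_top_terms=3)
            common = up_a & up_b
            kept = oracles.go_filter(terms, common, set(genes))[:3]
            expected = common & set().union(*(terms[t] for t in kept)) if kept else set()
            assert usps.genes == frozenset(expected)


class TestGenesetShift:
    def test_planted_shift_detected(self, rng):
        values = pd.Series(rng.normal(0, 1, 400),
                           index=[f"g{i}" for i in range(400)])
        shifted = [f"g{i}" for i in range(200)]
        values.loc[shifted] += 1.0
        res = geneset_shift(values, shifted)
        assert res.ks_p < 1e-6 and res.wilcoxon_p < 1e-6
        assert res.direction == 1

    def test_identical_constants(self):
        values = pd.Series(2.0, index=[f"g{i}" for i in range(20)])
        res = geneset_shift(values, [f"g{i}" for i in range(10)])
        assert res.ks_statistic == 0.0
        assert res.ks_p == 1.0 and res.wilcoxon_p == 1.0
        assert res.direction == 0

    def test_set_vs_all_background(self, rng):
        values = pd.Series(rng.normal(size=100),
                           index=[f"g{i}" for i in range(100)])
        res = geneset_shift(values, [f"g{i}" for i in range(10)],
                            background="all")
        assert 0 <= res.ks_p <= 1


class TestRedExpressionCorrelation:
    def test_perfect_anticorrelation(self):
        reds = pd.Series([0.3, 0.1, -0.1, -0.3], index=list("abcd"))
        expr = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert red_expression_correlation(reds, expr) == pytest.approx(-1.0)

    def test_constant_expression_nan(self):
        reds = pd.Series([0.3, 0.1, -0.1], index=list("abc"))
        expr = pd.Series(1.0, index=list("abc"))
        assert np.isnan(red_expression_correlation(reds, expr))

    def test_too_few_samples_nan(self):
        reds = pd.Series([0.3, 0.1], index=list("ab"))
        expr = pd.Series([1.0, 2.0], index=list("ab"))
        assert np.isnan(red_expression_correlation(reds, expr))

    def test_per_gene_screen_selects_coupled_genes(self, rng):
        samples = list("abcdefgh")
        expr = pd.Series(np.linspace(0, 1, 8), index=samples)
        n = 100
        mat = pd.DataFrame(rng.normal(0, 1, size=(n, 8)),
                           index=[f"g{i}" for i in range(n)], columns=samples)
        coupled = [f"g{i}" for i in range(5)]
        for g in coupled:
            mat.loc[g] = -3 * expr + rng.normal(0, 0.05, 8)
        r, selected, threshold = per_gene_red_correlation(mat, expr,
                                                          bottom_fraction=0.05)
        assert set(selected) == set(coupled)
        assert threshold < -0.9
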