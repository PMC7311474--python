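"""RED statistics, IPA, binning, direction tallies, minimal DE."""
import math

import numpy as np
import pandas as pd
import pytest

import oracles
from scapa._stats import fisher_pvalue
from scapa.apa_metrics import (IsoformPair, bin_by_autr, diff_expression,
                               ipa_analysis, normalize_red, red_3reads,
                               red_rnaseq, select_top2, tally_direction)
from scapa.pas_reads import PasCluster


def make_pair(ref_counts, test_counts, gene="G"):
    return IsoformPair(gene, 100, 500, {"ref": ref_counts, "test": test_counts})


class TestFisherAgainstOracle:
    def test_exhaustive_small_margins(self):
        """Package Fisher p equals hypergeometric enumeration, margins <= 12."""
        worst = 0.0
        for r1 in range(13):
            for r2 in range(13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        p_pkg = fisher_pvalue([[a, r1 - a], [c, r2 - c]])
                        p_orc = oracles.fisher_two_sided(a, r1 - a, c, r2 - c)
                        worst = max(worst, abs(p_pkg - p_orc))
        assert worst < 1e-10

    def test_zero_margin_uninformative(self):
        assert fisher_pvalue([[0, 0], [5, 3]]) == 1.0
        assert fisher_pvalue([[0, 4], [0, 3]]) == 1.0


class TestRed3Reads:
    def test_worked_example(self):
        res = red_3reads(make_pair((100, 100), (200, 50)), "ref", "test")
        expected_red = math.log2(50.5 / 200.5) - math.log2(100.5 / 100.5)
        assert res.red == pytest.approx(expected_red, abs=1e-12)
        assert res.red == pytest.approx(-1.989, abs=1e-3)
        assert res.abundance_change == pytest.approx(-0.3, abs=1e-12)
        assert res.p_value == pytest.approx(
            oracles.fisher_two_sided(100, 100, 200, 50), abs=1e-10)
        assert res.call == "shortened"

    def test_identity(self):
        res = red_3reads(make_pair((50, 50), (50, 50)), "ref", "test")
        assert res.red == 0.0
        assert res.p_value == 1.0
        assert res.call == "unchanged"

    def test_antisymmetry(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 400, 4))
            fwd = red_3reads(make_pair((a, b), (c, d)), "ref", "test")
            rev = red_3reads(make_pair((c, d), (a, b)), "ref", "test")
            assert rev.red == pytest.approx(-fwd.red, abs=1e-12)
            assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-12)

    def test_sig_rule_dialects(self):
        # big odds change (red ~ +1.37) but distal-fraction change only 3%
        pair = make_pair((980, 20), (950, 50))
        by_abundance = red_3reads(pair, "ref", "test", sig_rule="abundance5")
        by_ratio = red_3reads(pair, "ref", "test", sig_rule="ratio20")
        assert by_abundance.call == "unchanged"
        assert by_ratio.call == "lengthened"

    def test_zero_row_gives_p1_unchanged(self):
        res = red_3reads(make_pair((0, 0), (10, 30)), "ref", "test")
        assert res.p_value == 1.0 and res.call == "unchanged"


class TestRedRnaseq:
    def test_worked_example(self):
        res = red_rnaseq((300, 300), (300, 75), n_boot=20, seed=0)
        expected = math.log2(75.5 / 300.5) - math.log2(300.5 / 300.5)
        assert res.red == pytest.approx(expected, abs=1e-12)
        assert res.red == pytest.approx(-1.993, abs=1e-3)
        assert res.call == "shortened"

    def test_equal_ratios_zero(self):
        assert red_rnaseq((200, 100), (400, 200)).red == pytest.approx(0.0, abs=2e-3)

    def test_depth_invariance(self):
        shallow = red_rnaseq((300, 300), (300, 75))
        deep = red_rnaseq((300, 300), (3000, 750))
        # pseudocount is the only depth-sensitive term
        assert deep.red == pytest.approx(shallow.red, abs=1e-2)

    def test_bootstrap_sd_matches_delta_method(self):
        c, a = 400, 300
        res = red_rnaseq((c, a), (c, a), n_boot=200, seed=7)
        # binomial delta method: var(log2 a/c) ~ (1/a + 1/c - 2/n)/ln2^2 per sample
        per_sample = (1 / a + 1 / c - 2 / (a + c)) / math.log(2) ** 2
        expected_sd = math.sqrt(2 * per_sample)
        assert expected_sd / 2 < res.sd < expected_sd * 2

    def test_replicated_welch_path(self):
        ref = [(300, 290), (310, 305), (295, 300)]
        test = [(300, 150), (305, 140), (298, 160)]
        res = red_rnaseq(ref, test)
        assert res.red < -0.8
        assert res.p_value < 0.01
        assert res.call == "shortened"

    def test_replicated_identical_groups_p1(self):
        grp = [(100, 100), (100, 100)]
        res = red_rnaseq(grp, grp)
        assert res.red == 0.0 and res.p_value == 1.0


class TestSelectTop2:
    def _cluster(self, pos, counts, strand="+"):
        return PasCluster("chr1", strand, pos, (pos,), counts)

    def test_top2_by_pooled_count_ordered_by_position(self):
        clusters = [
            self._cluster(100, {"ref": 60, "test": 40}),   # A (5') 100
            self._cluster(300, {"ref": 40, "test": 40}),   # B     80
            self._cluster(500, {"ref": 50, "test": 40}),   # C (3') 90
        ]
        pair = select_top2(clusters, "ref", "test")
        assert (pair.ppas_position, pair.dpas_position) == (100, 500)

    def test_tie_is_deterministic_five_prime_first(self):
        clusters = [
            self._cluster(100, {"ref": 25, "test": 25}),
            self._cluster(300, {"ref": 25, "test": 25}),
            self._cluster(500, {"ref": 5, "test": 5}),
        ]
        pair = select_top2(clusters, "ref", "test")
        assert (pair.ppas_position, pair.dpas_position) == (100, 300)

    def test_min_read_guard_excludes_gene(self):
        clusters = [
            self._cluster(100, {"ref": 2, "test": 2}),   # 4 pooled < 5
            self._cluster(500, {"ref": 2, "test": 1}),   # 3 pooled < 5
        ]
        assert select_top2(clusters, "ref", "test") is None

    def test_minus_strand_orientation(self):
        clusters = [
            self._cluster(100, {"ref": 50, "test": 50}, strand="-"),
            self._cluster(500, {"ref": 50, "test": 50}, strand="-"),
        ]
        pair = select_top2(clusters, "ref", "test")
        # on '-' the proximal (5'-most) site has the larger coordinate
        assert (pair.ppas_position, pair.dpas_position) == (500, 100)


class TestIpa:
    def test_activation_example(self):
        res = ipa_analysis({"ref": 10, "test": 50}, {"ref": 90, "test": 50},
                           "ref", "test")
        assert res.call == "activated"
        assert res.abundance_change == pytest.approx(0.4, abs=1e-12)
        assert res.p_value == pytest.approx(
            oracles.fisher_two_sided(90, 10, 50, 50), abs=1e-10)

    def test_symmetric_swap_is_suppression(self):
        fwd = ipa_analysis({"ref": 10, "test": 50}, {"ref": 90, "test": 50},
                           "ref", "test")
        rev = ipa_analysis({"ref": 50, "test": 10}, {"ref": 50, "test": 90},
                           "ref", "test")
        assert rev.call == "suppressed"
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-12)
        assert rev.log2_ratio_change == pytest.approx(-fwd.log2_ratio_change,
                                                      abs=1e-12)

    def test_no_intronic_reads_excluded(self):
        assert ipa_analysis({"ref": 0, "test": 0}, {"ref": 90, "test": 50},
                            "ref", "test") is None


class TestBinByAutr:
    def test_equal_sized_bins(self):
        lengths = pd.Series(range(1, 11), index=[f"g{i}" for i in range(10)])
        metric = pd.Series(0.0, index=lengths.index)
        table, _ = bin_by_autr(metric, lengths, n_bins=5)
        assert list(table["n"]) == [2, 2, 2, 2, 2]
        assert list(table["max_autr"]) == [2, 4, 6, 8, 10]

    def test_monotone_metric_gives_monotone_medians(self):
        lengths = pd.Series(np.arange(1, 101) * 30.0,
                            index=[f"g{i}" for i in range(100)])
        metric = -0.001 * lengths
        table, p = bin_by_autr(metric, lengths, n_bins=5)
        meds = table["median"].to_numpy()
        assert np.all(np.diff(meds) < 0)
        assert p < 0.01

    def test_all_equal_metric(self):
        lengths = pd.Series(np.arange(1, 51), index=[f"g{i}" for i in range(50)])
        metric = pd.Series(0.7, index=lengths.index)
        table, p = bin_by_autr(metric, lengths)
        assert np.allclose(table["median"], 0.7)
        assert p == 1.0

    def test_ties_stay_in_lower_bin(self):
        lengths = pd.Series([1, 2, 2, 2, 3, 4, 5, 6, 7, 8],
                            index=[f"g{i}" for i in range(10)])
        metric = pd.Series(0.0, index=lengths.index)
        table, _ = bin_by_autr(metric, lengths, n_bins=5)
        # the run of 2s spans the bin-1/bin-2 boundary and stays in bin 1
        assert table.loc[1, "n"] == 4


class TestTallyAndNormalize:
    def test_tally_example(self):
        t = tally_direction(["shortened", "shortened", "lengthened", "unchanged"])
        assert (t.n_shortened, t.n_lengthened) == (2, 1)
        assert t.ratio == 2.0

    def test_no_significant_ratio_nan(self):
        t = tally_direction(["unchanged", "unchanged"])
        assert (t.n_shortened, t.n_lengthened) == (0, 0)
        assert math.isnan(t.ratio)

    @pytest.mark.parametrize("values,mode,expected", [
        ((-0.1, 0.0, 0.1), "mean", (-0.1, 0.0, 0.1)),
        ((1, 2, 3), "mean", (-1, 0, 1)),
        ((1, 2, 10), "median", (-1, 0, 8)),
    ])
    def test_normalize_red(self, values, mode, expected):
        out = normalize_red(pd.Series(values), mode=mode)
        assert np.allclose(out, expected)

    def test_normalize_needs_two_samples(self):
        with pytest.raises(ValueError):
            normalize_red(pd.Series([1.0]))


class TestDiffExpression:
    def _counts(self, gene_ref, gene_test, n_other=50, other=200):
        idx = ["target"] + [f"o{i}" for i in range(n_other)]
        return pd.DataFrame({
            "ref": [gene_ref] + [other] * n_other,
            "test": [gene_test] + [other] * n_other,
        }, index=idx)

    def test_no_change(self):
        df = diff_expression(self._counts(100, 100), ["ref"], ["test"])
        assert df.loc["target", "call"] == "unchanged"
        assert df.loc["target", "log2fc"] == pytest.approx(0.0, abs=0.01)

    def test_threefold_up_with_fisher_oracle(self):
        counts = self._counts(100, 300)
        df = diff_expression(counts, ["ref"], ["test"])
        # libraries: equalize sizes so size factors stay near 1
        lib_ref = int(counts["ref"].sum())
        lib_test = int(counts["test"].sum())
        p_orc = oracles.fisher_two_sided(100, lib_ref - 100, 300, lib_test - 300)
        assert df.loc["target", "p_value"] == pytest.approx(p_orc, abs=1e-10)
        assert df.loc["target", "log2fc"] == pytest.approx(1.58, abs=0.05)
        assert df.loc["target", "call"] == "up"

    def test_depth_scaling_leaves_fold_changes(self):
        counts = self._counts(100, 300)
        doubled = counts.copy()
        doubled["test"] = doubled["test"] * 2
        fc1 = diff_expression(counts, ["ref"], ["test"])["log2fc"]
        fc2 = diff_expression(doubled, ["ref"], ["test"])["log2fc"]
        # exact up to the fixed pseudocount on the rescaled normalized counts
        assert np.allclose(fc1, fc2, atol=1e-2)

    def test_replicated_welch_path(self, rng):
        idx = [f"g{i}" for i in range(40)]
        base = rng.integers(100, 300, 40)
        counts = pd.DataFrame({
            "r1": base, "r2": base + rng.integers(0, 10, 40),
            "t1": base, "t2": base + rng.integers(0, 10, 40),
        }, index=idx)
        counts.loc["g0", ["t1", "t2"]] = (base[0] * 4, base[0] * 4)
        df = diff_expression(counts, ["r1", "r2"], ["t1", "t2"])
        assert df.loc["g0", "log2fc"] > 1.5
        assert df.loc["g0", "p_value"] < 0.05
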