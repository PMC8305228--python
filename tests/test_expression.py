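"""log2CPM normalization, cutoff detection, expression calls, pathway coverage."""

import numpy as np
import pandas as pd
import pytest

from sipquant.expression import (
    ABSENT,
    COMPLETE,
    INCOMPLETE,
    determine_cutoff,
    expressed_genes,
    log2cpm,
    pathway_coverage,
)
from sipquant.simulate import simulate_counts


class TestLog2CPM:
    def test_definition_without_pseudocount(self):
        counts = pd.DataFrame({"s1": [1000, 999000]}, index=["g1", "g2"])
        vals = log2cpm(counts, pseudocount=0.0)
        assert vals.loc["g1", "s1"] == pytest.approx(np.log2(1000), abs=1e-9)

    def test_pseudocount_on_zero_count(self):
        counts = pd.DataFrame({"s1": [0, 10**6]}, index=["g1", "g2"])
        vals = log2cpm(counts, pseudocount=0.5)
        expected = np.log2(0.5 / (10**6 + 1.0) * 1e6)
        assert vals.loc["g1", "s1"] == pytest.approx(expected, abs=1e-6)

    def test_equal_counts_equal_values_within_sample(self):
        counts = pd.DataFrame({"s1": [5, 5, 5]}, index=list("abc"))
        vals = log2cpm(counts)
        assert vals["s1"].nunique() == 1

    def test_zero_library_size_names_sample(self):
        counts = pd.DataFrame({"good": [1, 2], "empty": [0, 0]})
        with pytest.raises(ValueError, match="empty"):
            log2cpm(counts)

    def test_scaling_a_sample_preserves_ranks(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"s1": rng.integers(0, 1000, 50)})
        scaled = counts * 7
        a = log2cpm(counts)["s1"].rank()
        b = log2cpm(scaled)["s1"].rank()
        pd.testing.assert_series_equal(a, b)


class TestDetermineCutoff:
    def test_bimodal_valley_located_between_modes(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(-2.0, 0.7, 3000), rng.normal(6.0, 1.0, 3000)]
        )
        res = determine_cutoff(values)
        assert res.method == "valley"
        assert -1.0 < res.cutoff < 5.0
        # near the brute-force density minimum on a fine grid
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(values, bw_method="silverman")
        grid = np.linspace(-1.0, 5.0, 2001)
        brute = grid[np.argmin(kde(grid))]
        assert res.cutoff == pytest.approx(brute, abs=0.25)

    def test_unimodal_falls_back_to_percentile(self):
        rng = np.random.default_rng(2)
        values = rng.normal(3.0, 1.0, 2000)
        res = determine_cutoff(values)
        assert res.method == "percentile-fallback"
        assert res.cutoff == pytest.approx(np.percentile(values, 5))

    def test_manual_override_always_wins(self):
        assert determine_cutoff([0.0] * 5, manual=1.0).cutoff == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="100"):
            determine_cutoff(np.zeros(50))


class TestExpressedGenes:
    @pytest.fixture()
    def lcpm(self):
        return pd.DataFrame(
            {
                "s1": [5.0, 5.0, 0.0],
                "s2": [5.0, 5.0, 0.0],
                "s3": [5.0, 0.0, 0.0],
                "s4": [0.0, 0.0, 0.0],
                "s5": [0.0, 0.0, 0.0],
                "s6": [0.0, 0.0, 0.0],
            },
            index=["three_hits", "two_hits", "none"],
        )

    def test_at_least_three_samples_rule(self, lcpm):
        calls = expressed_genes(lcpm, cutoff=1.0, min_samples=3)
        assert bool(calls.expressed["three_hits"]) is True
        assert bool(calls.expressed["two_hits"]) is False

    def test_min_samples_one(self, lcpm):
        calls = expressed_genes(lcpm, cutoff=1.0, min_samples=1)
        assert bool(calls.expressed["two_hits"]) is True
        assert bool(calls.expressed["none"]) is False

    def test_min_samples_out_of_range(self, lcpm):
        with pytest.raises(ValueError):
            expressed_genes(lcpm, cutoff=1.0, min_samples=7)


class TestPathwayCoverage:
    def _calls(self, expressed, universe):
        flags = pd.Series({g: g in expressed for g in universe})
        from sipquant.expression import ExpressionCallSet

        return ExpressionCallSet(expressed=flags, cutoff=1.0, min_samples=3)

    def test_three_of_four_ratio(self):
        calls = self._calls({"a", "b", "c"}, ["a", "b", "c", "d"])
        pm = pd.DataFrame({"pathway": ["P"] * 4, "gene": list("abcd")})
        out = pathway_coverage(calls, pm)
        assert out.iloc[0]["ratio"] == 0.75
        assert out.iloc[0]["status"] == COMPLETE

    def test_zero_expressed_is_absent(self):
        calls = self._calls(set(), list("abcde"))
        pm = pd.DataFrame({"pathway": ["P"] * 5, "gene": list("abcde")})
        assert pathway_coverage(calls, pm).iloc[0]["status"] == ABSENT

    def test_full_coverage_complete(self):
        calls = self._calls(set("abcde"), list("abcde"))
        pm = pd.DataFrame({"pathway": ["P"] * 5, "gene": list("abcde")})
        row = pathway_coverage(calls, pm).iloc[0]
        assert row["ratio"] == 1.0 and row["status"] == COMPLETE

    def test_partial_below_threshold_incomplete(self):
        calls = self._calls({"a"}, list("abcd"))
        pm = pd.DataFrame({"pathway": ["P"] * 4, "gene": list("abcd")})
        assert pathway_coverage(calls, pm).iloc[0]["status"] == INCOMPLETE

    def test_per_genome_universes_independent(self):
        calls = self._calls({"a1", "a2"}, ["a1", "a2", "b1", "b2"])
        pm = pd.DataFrame(
            {
                "pathway": ["P", "P", "P", "P"],
                "gene": ["a1", "a2", "b1", "b2"],
                "genome": ["A", "A", "B", "B"],
            }
        )
        out = pathway_coverage(calls, pm).set_index("genome")
        assert out.loc["A", "ratio"] == 1.0
        assert out.loc["B", "ratio"] == 0.0

    def test_adding_expressed_gene_never_decreases_ratio(self):
        universe = list("abcdef")
        pm = pd.DataFrame({"pathway": ["P"] * 6, "gene": universe})
        previous = -1.0
        expressed = set()
        for g in universe:
            expressed.add(g)
            ratio = pathway_coverage(self._calls(expressed, universe), pm).iloc[0]["ratio"]
            assert ratio >= previous
            previous = ratio

    def test_pathway_with_missing_gene_named(self):
        calls = self._calls(set(), ["a"])
        pm = pd.DataFrame({"pathway": ["Pbad"], "gene": [np.nan]})
        with pytest.raises(ValueError, match="Pbad"):
            pathway_coverage(calls, pm)


class TestEndToEndRecovery:
    def test_expressed_set_f1_at_six_log2_separation(self):
        counts, truth, _ = simulate_counts(
            n_genes=1500, n_samples=6, expressed_fraction=0.5, mode_separation=6.0, seed=4
        )
        lcpm = log2cpm(counts)
        cut = determine_cutoff(lcpm.to_numpy().ravel())
        calls = expressed_genes(lcpm, cut.cutoff, min_samples=3)
        predicted = calls.expressed_set
        tp = len(predicted & truth)
        precision = tp / max(len(predicted), 1)
        recall = tp / len(truth)
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.95
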