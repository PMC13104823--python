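from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cndiscord.geneset_analysis import (binned_set_log2fc,
                                        four_bin_comparison, ora_enrichment,
                                        rank_cumulative)
from cndiscord.io_formats import GeneSet


def _records(lfc, genes=None):
    genes = genes or [f"G{i}" for i in range(len(lfc))]
    return pd.DataFrame({"log2fc": lfc, "p_adj": 1.0},
                        index=pd.Index(genes, name="gene_id"))


class TestFourBin:
    def test_hand_tally(self):
        genes = [f"G{i}" for i in range(8)]
        lfc = [1.0, 0.5, -0.5, -1.0, 2.0, -2.0, 0.2, -0.2]
        ce = {"G0", "G2", "G4", "G5"}
        out = four_bin_comparison(_records(lfc, genes), genes, ce)
        assert out["n_ce_up"] == 2      # G0, G4
        assert out["n_ce_down"] == 2    # G2, G5
        assert out["n_other_up"] == 2   # G1, G6
        assert out["n_other_down"] == 2
        assert out["n_genes"] == 8

    def test_zero_fc_goes_to_down_class(self):
        out = four_bin_comparison(_records([0.0, 1.0], ["A", "B"]),
                                  ["A", "B"], {"A"})
        assert out["n_ce_down"] == 1 and out["n_ce_up"] == 0

    def test_all_up_leaves_down_undefined(self):
        genes = ["A", "B", "C", "D"]
        out = four_bin_comparison(_records([1.0, 2.0, 1.5, 0.5], genes),
                                  genes, {"A", "B"})
        assert np.isnan(out["p_down"])
        assert np.isfinite(out["p_up"])

    def test_null_calibration(self, rng):
        """CE and other drawn from one distribution: p_up uniform.
        KS against uniform over 200 null simulations not rejected at 0.01."""
        pvals = []
        genes = [f"G{i}" for i in range(40)]
        ce = set(genes[:15])
        for _ in range(200):
            lfc = rng.normal(1.0, 0.5, size=40)  # all up
            out = four_bin_comparison(_records(list(lfc), genes), genes, ce)
            pvals.append(out["p_up"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRankCumulative:
    def test_ce_on_top_extreme(self):
        genes = [f"G{i}" for i in range(10)]
        lfc = list(range(10, 0, -1))
        ce = set(genes[:3])  # the three highest log2fc
        out = rank_cumulative(_records(lfc, genes), genes, ce)
        assert out["cum_fraction"].iloc[2] == 1.0
        # maximal deviation for 3 CE of 10: reached at rank 3
        assert out.attrs["deviation"] == pytest.approx(1.0 - 3 / 10)

    def test_curve_monotone_ends_at_one(self, rng):
        genes = [f"G{i}" for i in range(25)]
        ce = set(rng.choice(genes, 8, replace=False))
        out = rank_cumulative(_records(list(rng.normal(0, 1, 25)), genes),
                              genes, ce)
        cum = out["cum_fraction"].to_numpy()
        assert (np.diff(cum) >= 0).all() and cum[-1] == 1.0
        assert 0 <= out.attrs["deviation"] <= 1

    def test_all_genes_ce_zero_deviation(self):
        genes = ["A", "B", "C"]
        out = rank_cumulative(_records([1.0, 0.0, -1.0], genes), genes,
                              set(genes))
        assert out.attrs["deviation"] == 0.0

    def test_mean_deviation_matches_enumeration(self):
        """Average deviation over every C(10,3) CE placement equals the
        enumeration expectation computed without the implementation."""
        genes = [f"G{i}" for i in range(10)]
        lfc = list(range(10, 0, -1))  # fixed ranking
        rec = _records(lfc, genes)
        expected = []
        observed = []
        for placement in combinations(range(10), 3):
            # independent oracle: walk the ranking, count CE by hand
            cum, dev, seen = [], 0.0, 0
            for rank in range(10):
                if rank in placement:
                    seen += 1
                dev = max(dev, abs(seen / 3 - (rank + 1) / 10))
            expected.append(dev)
            ce = {genes[i] for i in placement}
            observed.append(rank_cumulative(rec, genes, ce).attrs["deviation"])
        assert np.allclose(observed, expected)
        assert np.mean(observed) == pytest.approx(np.mean(expected))

    def test_no_ce_raises(self):
        genes = ["A", "B"]
        with pytest.raises(ValueError):
            rank_cumulative(_records([1.0, 0.0], genes), genes, {"Z"})


class TestBinnedSetLog2FC:
    def test_dosage_ordering_all_genes(self, small_result):
        res, aset, truth = small_result
        out = binned_set_log2fc(res.records, res.summaries, aset.genes, "all")
        assert (out["mean_log2fc_loss"] < out["mean_log2fc_nc"]
                < out["mean_log2fc_gain"])
        assert out["p_gain_vs_loss"] < 1e-6

    def test_discordant_program_flat(self, small_result):
        res, aset, truth = small_result
        out = binned_set_log2fc(res.records, res.summaries,
                                truth.program_genes, "program")
        means = [out[f"mean_log2fc_{b}"] for b in ("loss", "nc", "gain")]
        assert max(means) - min(means) < 0.5
        assert all(m > 1.0 for m in means)

    def test_empty_loss_bin_skips_test(self):
        rec = _records([0.5, 0.6], ["A", "B"])
        summ = pd.DataFrame({"bin": ["nc", "gain"], "mean_cna": [0.0, 0.6]},
                            index=["A", "B"])
        out = binned_set_log2fc(rec, summ, ["A", "B"])
        assert out["test_skipped"] and np.isnan(out["p_gain_vs_loss"])

    def test_full_universe_matches_bin_proportion_means(self, small_result):
        """Cross-module consistency: all-genes bin means equal means computed
        directly from the concordance join."""
        res, aset, truth = small_result
        out = binned_set_log2fc(res.records, res.summaries, aset.genes)
        df = res.records.join(res.summaries[["bin"]], how="inner")
        for b in ("loss", "nc", "gain"):
            direct = df.loc[df["bin"] == b, "log2fc"].mean()
            assert out[f"mean_log2fc_{b}"] == pytest.approx(direct)


class TestORA:
    def test_exact_set_ranks_first(self):
        universe = [f"g{i}" for i in range(100)]
        sets = [GeneSet("hit", "", frozenset(universe[:6])),
                GeneSet("miss", "", frozenset(universe[50:70]))]
        table = ora_enrichment(universe[:6], sets, universe)
        assert table.index[0] == "hit"
        assert table.loc["hit", "n_overlap"] == 6

    def test_matches_enumeration(self):
        """N=20, |set|=5, |list|=6, k=4: p from exhaustive draw counting."""
        universe = [f"g{i}" for i in range(20)]
        gs = GeneSet("s", "", frozenset(universe[:5]))
        query = universe[:4] + universe[10:12]  # overlap 4
        table = ora_enrichment(query, [gs], universe)
        hits = sum(1 for draw in combinations(range(20), 6)
                   if len(set(draw) & set(range(5))) >= 4)
        assert table.loc["s", "p_value"] == pytest.approx(hits / comb(20, 6))

    def test_no_overlap_adjusted_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        sets = [GeneSet(f"s{j}", "", frozenset(universe[30 + j * 5: 35 + j * 5]))
                for j in range(4)]
        table = ora_enrichment(universe[:5], sets, universe)
        assert (table["p_adj"] > 0.99).all()

    def test_adjusted_monotone_in_raw(self, rng):
        universe = [f"g{i}" for i in range(60)]
        sets = [GeneSet(f"s{j}", "",
                        frozenset(rng.choice(universe, 10, replace=False)))
                for j in range(8)]
        table = ora_enrichment(universe[:12], sets, universe)
        ordered = table.sort_values("p_value")
        assert ordered["p_adj"].is_monotonic_increasing

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(["zz"], [GeneSet("s", "", frozenset({"g1"}))],
                           ["g1", "g2"])
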