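#!/usr/bin/env python
"""Discordant genes: upregulated despite copy-number loss, and how shared.

Re-runs the per-cancer analyses in memory, extracts genes upregulated at
the strict tier (log2FC > 1, adjusted p < 1e-4) inside loss regions,
compares them with the planted truth, counts how many cancers share each
gene, and tests pairwise overlaps within shared regions (hypergeometric).
Writes results/03_discordant_summary.csv, 03_sharing_histogram.csv and
03_pairwise_overlaps.csv.
"""

import json
from pathlib import Path

import pandas as pd

from cndiscord.concordance import bin_tier_proportions
from cndiscord.io_formats import read_matrix_tsv, read_probemap
from cndiscord.pipeline import (Thresholds, analyze_cancer, integrate_cancers)
from cndiscord.preprocess import build_analysis_set, classify_samples

ROOT = Path(__file__).resolve().parents[1]
CANCERS = ["SYNA", "SYNB", "SYNC"]


def load_results():
    sim = ROOT / "scratch" / "sim"
    results, truths = {}, {}
    for cancer in CANCERS:
        expr = read_matrix_tsv(sim / cancer / "expr.tsv", "expression_log2")
        cna = read_matrix_tsv(sim / cancer / "cna.tsv", "cna_thresholded")
        annotations = read_probemap(sim / cancer / "probemap.tsv")
        samples = classify_samples(expr.sample_ids, cancer_code=cancer)
        aset = build_analysis_set(expr, cna, samples, annotations,
                                  cancer_code=cancer)
        results[cancer] = analyze_cancer(aset)
        truths[cancer] = json.loads((sim / cancer / "truth.json").read_text())
    return results, truths


def main():
    results, truths = load_results()
    cross = integrate_cancers(results)
    res_dir = ROOT / "results"
    res_dir.mkdir(exist_ok=True)

    rows = []
    for cancer, r in results.items():
        called = set(cross["discordant"][cancer].index)
        planted = set(truths[cancer]["discordant"])
        props = bin_tier_proportions(r.records, r.summaries)
        rows.append({
            "cancer": cancer,
            "n_discordant_called": len(called),
            "n_planted": len(planted),
            "n_recovered": len(called & planted),
            "loss_bin_prop_up": round(props.loc["loss", "prop_up"], 4),
            "nc_bin_prop_up": round(props.loc["nc", "prop_up"], 4),
        })
        print(f"{cancer}: {len(called)} discordant genes called, "
              f"{len(called & planted)}/{len(planted)} planted recovered")
    pd.DataFrame(rows).to_csv(res_dir / "03_discordant_summary.csv",
                              index=False)

    cross["sharing_histogram"].rename("n_genes").to_csv(
        res_dir / "03_sharing_histogram.csv")
    shared_frac = (cross["sharing_per_gene"]["n_cancers"] >= 2).mean()
    print(f"sharing: {shared_frac:.1%} of discordant genes appear in >=2 cancers")

    overlaps = cross["pairwise_overlaps"]
    overlaps.to_csv(res_dir / "03_pairwise_overlaps.csv", index=False)
    tested = overlaps[overlaps["tested"]]
    if len(tested):
        print(f"pairwise overlap tests: {len(tested)} tested, "
              f"min p = {tested['p_value'].min():.3g}")


if __name__ == "__main__":
    main()
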