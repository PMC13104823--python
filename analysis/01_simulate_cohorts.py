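#!/usr/bin/env python
"""Simulate three TCGA-like cancers with shared planted loss regions.

All three cancers carry the same two arm-scale loss regions (chr1, chr2)
and one gain region (chr3), but draw their own carrier tumors, noise and
discordant-gene picks, emulating recurrent deletions shared across cancer
types with mostly cancer-private upregulated genes. Matrices and probemaps
go to scratch/sim/<CANCER>/ (pipeline inputs); a compact per-cancer summary
goes to results/01_cohorts.csv.
"""

import json
from pathlib import Path

import pandas as pd

from cndiscord.io_formats import write_matrix_tsv, write_probemap
from cndiscord.synthetic_data import default_truth_config, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
CANCERS = {"SYNA": 101, "SYNB": 102, "SYNC": 103}
N_GENES, N_TUMORS, N_NORMALS = 2000, 100, 20


def main():
    rows = []
    for cancer, seed in CANCERS.items():
        out = ROOT / "scratch" / "sim" / cancer
        out.mkdir(parents=True, exist_ok=True)
        cfg = default_truth_config(N_GENES, 5)
        cfg.n_discordant_per_region = 20  # richer lists for overlap testing
        expr, cna, annotations, samples, truth = generate_cohort(
            N_GENES, 5, N_TUMORS, N_NORMALS, cfg, seed)
        write_matrix_tsv(expr, out / "expr.tsv")
        write_matrix_tsv(cna, out / "cna.tsv")
        write_probemap(annotations.values(), out / "probemap.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump({"discordant": sorted(truth.discordant_genes),
                       "program": sorted(truth.program_genes),
                       "region_genes": truth.region_genes}, fh)
        rows.append({
            "cancer": cancer, "seed": seed, "n_genes": N_GENES,
            "n_tumors": N_TUMORS, "n_normals": N_NORMALS,
            "n_loss_regions": len(truth.loss_regions),
            "n_discordant": len(truth.discordant_genes),
            "n_low_expression": len(truth.low_expr_genes),
        })
        print(f"{cancer}: wrote {N_GENES}x{N_TUMORS + N_NORMALS} cohort, "
              f"{len(truth.discordant_genes)} planted discordant genes")
    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(res / "01_cohorts.csv", index=False)


if __name__ == "__main__":
    main()
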