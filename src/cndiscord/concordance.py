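"""Crossing copy-number bins with expression change.

This is the pipeline's central question: of the genes sitting in regions of
recurrent copy-number loss, which are nevertheless expressed *higher* in
tumor than normal (discordant genes)? Also provides the genome-wide
bin-by-direction proportions, cross-cancer sharing counts, and pairwise
hypergeometric overlap tests between cancers' discordant lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cna_regions import LossRegion
from .diffexpr import is_up


def bin_tier_proportions(records: pd.DataFrame, summaries: pd.DataFrame,
                         fc_cut: float = 1.0) -> pd.DataFrame:
    """Per copy-number bin, the fraction of genes whose tumor-vs-normal
    log2FC exceeds +fc_cut (up) or falls below -fc_cut (down).

    The cut is on fold change alone. Empty bins get NaN proportions and an
    `empty` flag.
    """
    df = records.join(summaries[["bin"]], how="inner")
    rows = []
    for b in ("loss", "nc", "gain"):
        sub = df[df["bin"] == b]
        n = len(sub)
        rows.append({
            "bin": b,
            "n_genes": n,
            "n_up": int((sub["log2fc"] > fc_cut).sum()),
            "n_down": int((sub["log2fc"] < -fc_cut).sum()),
            "prop_up": (sub["log2fc"] > fc_cut).mean() if n else np.nan,
            "prop_down": (sub["log2fc"] < -fc_cut).mean() if n else np.nan,
            "empty": n == 0,
        })
    return pd.DataFrame(rows).set_index("bin")


def discordant_genes(records: pd.DataFrame, regions: list[LossRegion],
                     tier: str = "strict") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes inside any loss region that are upregulated at the given tier.

    Returns (genes, per_region): `genes` has one row per discordant gene
    with its region memberships; `per_region` reports each region's number
    and fraction of upregulated genes.
    """
    up = is_up(records, tier)
    gene_rows: dict[str, list[str]] = {}
    region_rows = []
    for ridx, r in enumerate(regions):
        in_region = [g for g in r.gene_span if g in records.index]
        up_genes = [g for g in in_region if up.get(g, False)]
        region_rows.append({
            "region": f"{r.cancer_code}:{r.chromosome}:{r.start}-{r.end}",
            "cancer_code": r.cancer_code,
            "chromosome": r.chromosome,
            "rule": r.rule,
            "n_genes": len(in_region),
            "n_up": len(up_genes),
            "frac_up": len(up_genes) / len(in_region) if in_region else np.nan,
        })
        for g in up_genes:
            gene_rows.setdefault(g, []).append(region_rows[-1]["region"])
    genes = pd.DataFrame(
        {"regions": [";".join(v) for v in gene_rows.values()],
         "log2fc": [records.loc[g, "log2fc"] for g in gene_rows],
         "p_adj": [records.loc[g, "p_adj"] for g in gene_rows]},
        index=pd.Index(list(gene_rows), name="gene_id"),
    )
    return genes, pd.DataFrame(region_rows).set_index("region")


def sharing_histogram(lists_by_cancer: dict[str, set[str]],
                      annotations=None) -> tuple[pd.Series, pd.DataFrame]:
    """How often is each discordant gene shared across cancers?

    Returns (histogram, per_gene): histogram maps number-of-cancers -> gene
    count over the union of all lists; per_gene lists each gene's cancers.
    If `annotations` is given, per_gene carries the chromosome so callers
    can roll up shared fractions per chromosome.
    """
    if len(lists_by_cancer) < 2:
        raise ValueError("sharing analysis needs at least two cancers")
    union = sorted(set().union(*lists_by_cancer.values()))
    counts = {g: sum(g in s for s in lists_by_cancer.values()) for g in union}
    hist = pd.Series(counts, name="n_cancers").value_counts().sort_index()
    hist.index.name = "n_cancers"
    per_gene = pd.DataFrame({
        "n_cancers": [counts[g] for g in union],
        "cancers": [";".join(sorted(c for c, s in lists_by_cancer.items() if g in s))
                    for g in union],
    }, index=pd.Index(union, name="gene_id"))
    if annotations is not None:
        per_gene["chromosome"] = [
            annotations[g].chromosome if g in annotations else "NA" for g in union
        ]
    return hist, per_gene


def per_chromosome_sharing(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Roll sharing up per chromosome: total discordant genes and the
    fraction found in two or more cancers."""
    if "chromosome" not in per_gene.columns:
        raise ValueError("per_gene table lacks chromosome annotation")
    rows = []
    for chrom, sub in per_gene.groupby("chromosome"):
        rows.append({
            "chromosome": chrom,
            "n_genes": len(sub),
            "n_shared": int((sub["n_cancers"] >= 2).sum()),
            "frac_shared": (sub["n_cancers"] >= 2).mean(),
        })
    return pd.DataFrame(rows).set_index("chromosome")


@dataclass(frozen=True)
class OverlapTest:
    cancer_a: str
    cancer_b: str
    n_universe: int
    n_a: int
    n_b: int
    n_shared: int
    p_value: float


def pairwise_overlap_test(list_a: set[str], list_b: set[str],
                          universe: set[str], min_list: int = 15,
                          cancer_a: str = "A", cancer_b: str = "B",
                          ) -> OverlapTest | None:
    """Upper-tail hypergeometric test of the overlap between two cancers'
    upregulated-gene lists within a shared-region universe.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|A|, n=|B|): the
    chance of sharing at least the observed k genes if B were drawn at
    random from the universe. Returns None when either list is smaller than
    min_list (the test is not performed).
    """
    if not list_a <= universe or not list_b <= universe:
        raise ValueError("gene lists must be subsets of the universe")
    if len(list_a) < min_list or len(list_b) < min_list:
        return None
    k = len(list_a & list_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(list_a), len(list_b)))
    return OverlapTest(cancer_a, cancer_b, len(universe), len(list_a),
                       len(list_b), k, min(p, 1.0))
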