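"""Gene-set comparisons against copy number and expression change.

Three analyses of how a gene class behaves inside and around loss regions:

* four-bin comparison — split a region's genes by common-essential (CE)
  membership and by the sign of the tumor-vs-normal log2FC, then t-test CE
  against the rest within each direction;
* rank-cumulative curve — rank a region's genes from most up- to most
  downregulated and trace the cumulative fraction of CE genes, with a
  KS-style maximum deviation from the uniform diagonal as a scalar summary;
* binned set means — mean log2FC of a gene set within the genome-wide
  loss/nc/gain copy-number bins, with a gain-vs-loss t-test (flat means
  signal copy-number-independent expression change, the signature of the
  discordant programs);

plus a local hypergeometric over-representation test over GMT libraries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSet


def four_bin_comparison(records: pd.DataFrame, region_genes,
                        ce_set: frozenset[str] | set[str]) -> dict:
    """Classify a region's genes into {CE, other} x {T>N, T<N} and compare
    log2FC of CE vs other within each direction (Welch t-test).

    Genes with log2FC exactly 0 go to the T<N class. Contrasts where either
    class has fewer than two genes are flagged undefined (p NaN).
    """
    sub = records.loc[[g for g in region_genes if g in records.index]]
    lfc = sub["log2fc"]
    is_ce = sub.index.isin(ce_set)
    up = lfc > 0

    classes = {
        "ce_up": lfc[is_ce & up], "other_up": lfc[~is_ce & up],
        "ce_down": lfc[is_ce & ~up], "other_down": lfc[~is_ce & ~up],
    }

    def _p(a: pd.Series, b: pd.Series) -> float:
        if len(a) < 2 or len(b) < 2:
            return np.nan
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        return float(p) if np.isfinite(p) else 1.0

    out = {"n_genes": len(sub)}
    for name, vals in classes.items():
        out[f"n_{name}"] = len(vals)
        out[f"mean_{name}"] = float(vals.mean()) if len(vals) else np.nan
    out["p_up"] = _p(classes["ce_up"], classes["other_up"])
    out["p_down"] = _p(classes["ce_down"], classes["other_down"])
    return out


def rank_cumulative(records: pd.DataFrame, region_genes,
                    ce_set: frozenset[str] | set[str]) -> pd.DataFrame:
    """Cumulative CE fraction along genes ranked by log2FC (descending,
    ties broken by gene id), against the uniform diagonal.

    Returns one row per rank with columns gene_id, log2fc, is_ce,
    cum_fraction, expected, and attrs['deviation'] = max |observed -
    expected| (a Kolmogorov-style statistic for how early or late the CE
    genes sit in the ranking).
    """
    sub = records.loc[[g for g in region_genes if g in records.index]].copy()
    # descending log2fc, ties broken by ascending gene id
    sub = sub.iloc[np.lexsort((sub.index.to_numpy(), -sub["log2fc"].to_numpy()))]
    is_ce = sub.index.isin(ce_set)
    n_ce = int(is_ce.sum())
    if n_ce == 0:
        raise ValueError("no common-essential genes in region")
    n = len(sub)
    cum = np.cumsum(is_ce) / n_ce
    expected = np.arange(1, n + 1) / n
    out = pd.DataFrame({
        "log2fc": sub["log2fc"].to_numpy(),
        "is_ce": is_ce,
        "cum_fraction": cum,
        "expected": expected,
    }, index=sub.index)
    out.attrs["deviation"] = float(np.max(np.abs(cum - expected)))
    return out


def binned_set_log2fc(records: pd.DataFrame, summaries: pd.DataFrame,
                      gene_set, set_name: str = "") -> dict:
    """Mean tumor-vs-normal log2FC of a gene set within each genome-wide
    copy-number bin, with a gain-vs-loss Welch t-test.

    Bins with fewer than two set members are excluded from the test and
    flagged. Pass the full gene universe as the set for the all-genes
    baseline.
    """
    df = records.join(summaries[["bin"]], how="inner")
    df = df[df.index.isin(set(gene_set))]
    out: dict = {"set_name": set_name, "n_total": len(df)}
    by_bin = {}
    for b in ("loss", "nc", "gain"):
        vals = df.loc[df["bin"] == b, "log2fc"]
        by_bin[b] = vals
        out[f"n_{b}"] = len(vals)
        out[f"mean_log2fc_{b}"] = float(vals.mean()) if len(vals) else np.nan
    if len(by_bin["gain"]) >= 2 and len(by_bin["loss"]) >= 2:
        out["p_gain_vs_loss"] = float(
            stats.ttest_ind(by_bin["gain"], by_bin["loss"], equal_var=False).pvalue)
        out["test_skipped"] = False
    else:
        out["p_gain_vs_loss"] = np.nan
        out["test_skipped"] = True
    return out


def ora_enrichment(gene_list, gene_sets: list[GeneSet],
                   universe) -> pd.DataFrame:
    """Over-representation of a gene list in each gene set.

    Upper-tail hypergeometric p per set (sets are intersected with the
    universe first; sets disjoint from the universe are skipped), BH
    adjustment across tested sets, sorted by adjusted p then raw p.
    """
    universe = set(universe)
    query = set(gene_list)
    if not query <= universe:
        raise ValueError("gene list must be a subset of the universe")
    n = len(universe)
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        if not members:
            continue
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, n, len(members), len(query)))
        rows.append({"set_name": gs.name, "n_set": len(members),
                     "n_query": len(query), "n_overlap": k,
                     "p_value": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["set_name", "n_set", "n_query",
                                     "n_overlap", "p_value", "p_adj"]
                            ).set_index("set_name")
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["p_adj", "p_value"]).set_index("set_name")
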