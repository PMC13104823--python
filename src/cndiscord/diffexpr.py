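"""Per-gene tumor-vs-normal differential expression.

Two-sided two-sample t-tests on log2 expression (Welch by default, pooled
variance available), Benjamini-Hochberg adjustment over all tested genes in
a dataset, and classification into the two stringency tiers used throughout
the analysis:

    strict:  |log2FC| > 1.0 and adjusted p < 1e-4
    relaxed: |log2FC| > 0.4 and adjusted p < 0.01

A record's tier stores the most stringent tier met (strict genes also
satisfy the relaxed cut-offs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

STRICT_CUTOFF = (1.0, 1e-4)   # (|log2FC|, adjusted p)
RELAXED_CUTOFF = (0.4, 1e-2)


def differential_expression(expr_tumor: pd.DataFrame,
                            expr_normal: pd.DataFrame,
                            equal_var: bool = False) -> pd.DataFrame:
    """t-test every gene, tumor vs normal, on log2 values.

    Returns a DataFrame indexed by gene with columns mean_tumor, mean_normal,
    log2fc, p_value, p_adj, n_tumor, n_normal, tested. Genes with fewer than
    two observations in either group are flagged untested (p NaN) and
    excluded from the adjustment; zero-variance degenerate genes get p = 1.
    """
    genes = expr_tumor.index
    t_arr = expr_tumor.to_numpy(dtype=float)
    n_arr = expr_normal.to_numpy(dtype=float)
    n_t = np.sum(np.isfinite(t_arr), axis=1)
    n_n = np.sum(np.isfinite(n_arr), axis=1)
    with np.errstate(invalid="ignore"):
        mean_t = np.where(n_t > 0, np.nansum(np.nan_to_num(t_arr, nan=0.0), axis=1) / np.maximum(n_t, 1), np.nan)
        mean_n = np.where(n_n > 0, np.nansum(np.nan_to_num(n_arr, nan=0.0), axis=1) / np.maximum(n_n, 1), np.nan)
    tested = (n_t >= 2) & (n_n >= 2)

    pvals = np.full(len(genes), np.nan)
    if tested.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(t_arr[tested], n_arr[tested], axis=1,
                                  equal_var=equal_var, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
        # zero-variance degenerate genes: keep them in the bookkeeping at p=1
        p = np.where(np.isfinite(p), p, 1.0)
        pvals[tested] = p

    p_adj = np.full(len(genes), np.nan)
    if tested.any():
        p_adj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "log2fc": mean_t - mean_n,
            "p_value": pvals,
            "p_adj": p_adj,
            "n_tumor": n_t,
            "n_normal": n_n,
            "tested": tested,
        },
        index=genes,
    )


def classify_tiers(records: pd.DataFrame,
                   strict: tuple[float, float] = STRICT_CUTOFF,
                   relaxed: tuple[float, float] = RELAXED_CUTOFF) -> pd.DataFrame:
    """Add a `tier` column: up_strict / up_relaxed / down_strict /
    down_relaxed / none (most stringent tier met)."""
    fc_s, p_s = strict
    fc_r, p_r = relaxed
    lfc = records["log2fc"].to_numpy()
    padj = records["p_adj"].to_numpy()
    tier = np.full(len(records), "none", dtype=object)
    with np.errstate(invalid="ignore"):
        up_r = (lfc > fc_r) & (padj < p_r)
        up_s = (lfc > fc_s) & (padj < p_s)
        dn_r = (lfc < -fc_r) & (padj < p_r)
        dn_s = (lfc < -fc_s) & (padj < p_s)
    tier[up_r] = "up_relaxed"
    tier[up_s] = "up_strict"
    tier[dn_r] = "down_relaxed"
    tier[dn_s] = "down_strict"
    out = records.copy()
    out["tier"] = tier
    return out


def is_up(records: pd.DataFrame, tier: str = "strict") -> pd.Series:
    """Boolean mask of genes upregulated at the given tier ('strict' or
    'relaxed'; strict genes count as relaxed too)."""
    if tier == "strict":
        return records["tier"] == "up_strict"
    if tier == "relaxed":
        return records["tier"].isin(["up_strict", "up_relaxed"])
    raise ValueError(f"unknown tier {tier!r}")


def expression_by_copy_number(expr: pd.DataFrame, cna: pd.DataFrame,
                              expr_normal: pd.DataFrame,
                              gene: str) -> pd.DataFrame:
    """Partition one gene's tumor samples by integer copy-number call.

    Returns one row per group (normal, then CNA calls -2..+2 present) with
    n, median, q1, q3, mean and two-sided t-test p-values versus the normal
    group and versus the diploid (call 0) group. Contrasts against groups
    with fewer than two samples are reported as NaN.
    """
    if gene not in expr.index or gene not in cna.index:
        raise KeyError(f"gene {gene!r} absent from expression or CNA matrix")
    e = expr.loc[gene]
    c = cna.loc[gene]
    normal_vals = expr_normal.loc[gene].dropna().to_numpy() if gene in expr_normal.index else np.array([])

    groups: dict[str, np.ndarray] = {"normal": normal_vals}
    for call in (-2, -1, 0, 1, 2):
        vals = e[(c == call)].dropna().to_numpy()
        if len(vals):
            groups[str(call)] = vals

    def _p(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) < 2 or len(b) < 2:
            return np.nan
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        return float(p) if np.isfinite(p) else 1.0

    diploid = groups.get("0", np.array([]))
    rows = []
    for name, vals in groups.items():
        rows.append({
            "group": name,
            "n": len(vals),
            "median": float(np.median(vals)) if len(vals) else np.nan,
            "q1": float(np.percentile(vals, 25)) if len(vals) else np.nan,
            "q3": float(np.percentile(vals, 75)) if len(vals) else np.nan,
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "p_vs_normal": np.nan if name == "normal" else _p(vals, normal_vals),
            "p_vs_diploid": np.nan if name == "0" else _p(vals, diploid),
        })
    return pd.DataFrame(rows).set_index("group")
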