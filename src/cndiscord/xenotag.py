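"""Relative quantification of PCR-tagged cell lines in mixed xenografts.

Each tumor grows from a mix of cell pools carrying distinct genomic PCR
tags. qPCR cycle thresholds (Ct) for each tag, referenced to the time-zero
input mix, give each tag's relative abundance under the ideal-doubling
model: quantity = 2^dCt with dCt = Ct_reference - Ct_tumor (one fewer
cycle to threshold means twice the template). Per-tumor renormalization to
sum 1 turns quantities into proportions, which are compared to the null of
an even mix by the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def tag_proportions(ct: pd.DataFrame, reference_ct: pd.Series) -> pd.DataFrame:
    """Convert a tumors x tags Ct table into per-tumor tag proportions.

    `ct` has one row per tumor and one column per tag; `reference_ct` gives
    the time-zero mix's Ct per tag. Not-detected tags (NaN Ct) get quantity
    zero. Proportions sum to one within each tumor.
    """
    missing = [t for t in ct.columns if t not in reference_ct.index]
    if missing:
        raise ValueError(f"tags without a reference Ct: {missing}")
    if ct.shape[1] < 2:
        raise ValueError("need at least two tags per tumor")
    dct = reference_ct[ct.columns].to_numpy()[None, :] - ct.to_numpy(dtype=float)
    quantity = np.power(2.0, dct)
    quantity = np.where(np.isfinite(quantity), quantity, 0.0)  # not-detected -> 0
    totals = quantity.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = list(ct.index[(totals == 0).ravel()])
        raise ValueError(f"no tag detected in tumors {bad}")
    props = pd.DataFrame(quantity / totals, index=ct.index, columns=ct.columns)
    return props


def signed_rank_test(proportions, null: float = 0.5,
                     alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value for H0: median tag proportion = null.

    Exact distribution when n <= 25 and magnitudes are tie-free, otherwise
    the normal approximation. Differences exactly at the null are dropped
    (classic zero handling); if every value sits at the null, p = 1.
    """
    x = np.asarray(proportions, dtype=float)
    if len(x) < 5:
        raise ValueError("signed-rank test needs at least 5 tumors")
    d = x - null
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    tie_free = len(np.unique(np.abs(d))) == len(d)
    method = "exact" if (len(d) <= 25 and tie_free) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method,
                         zero_method="wilcox")
    return float(res.pvalue)


def read_ct_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format Ct CSV (tumor_id, site, tag, ct) into a wide
    tumors x tags Ct table plus a tumor metadata table."""
    df = pd.read_csv(path)
    required = {"tumor_id", "tag", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    wide = df.pivot(index="tumor_id", columns="tag", values="ct")
    meta_cols = [c for c in df.columns if c not in {"tag", "ct"}]
    meta = df[meta_cols].drop_duplicates("tumor_id").set_index("tumor_id")
    return wide, meta


def compare_mix(ct: pd.DataFrame, reference_ct: pd.Series,
                control_tag: str, null: float = 0.5,
                alternative: str = "two-sided") -> dict:
    """Proportions for every tumor plus the signed-rank comparison of the
    control tag's proportion against an even mix."""
    props = tag_proportions(ct, reference_ct)
    p = signed_rank_test(props[control_tag], null=null, alternative=alternative)
    return {
        "proportions": props,
        "control_tag": control_tag,
        "n_tumors": len(props),
        "n_control_majority": int((props[control_tag] > null).sum()),
        "p_value": p,
    }
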