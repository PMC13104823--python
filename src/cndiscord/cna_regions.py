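"""Per-gene copy-number summaries and recurrent-loss region calling.

A gene's copy-number state in a cohort is summarised as the arithmetic mean
of its GISTIC2-thresholded calls across tumor samples, and binned as
loss (< -0.4), gain (> +0.4) or nc otherwise.

A primary loss region is a maximal contiguous run of position-ordered genes
on one chromosome such that

  (a) the run's mean per-gene CNA is <= -0.4 (loss threshold),
  (b) it contains at least 100 expressed genes,
  (c) every gene inside has mean CNA < -0.35 (tolerance bound): genes in
      (-0.4, -0.35) are tolerated inside a run whose overall mean still
      qualifies, but no gene at or above -0.35 can sit inside a region.

Maximal means not extendable in either direction without violating (a) or
(c). A qualifying run with fewer than the minimum genes can still be
rescued if its genomic span is fully contained in another cancer's primary
region (cross-cancer recurrence).

The scan works on a prefix-sum reformulation: with Q[k] = sum(cna[:k]) -
loss_thr*k, a window [i, j] has mean <= loss_thr iff Q[j+1] <= Q[i]. Nested
qualifying windows are absorbed by containment-maximality; if two maximal
windows partially overlap (their union cannot qualify, by maximality) the
one with more genes is kept (ties: lower mean, then leftmost).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation

logger = logging.getLogger(__name__)

LOSS_THRESHOLD = -0.4
GAIN_THRESHOLD = 0.4
TOLERANCE = -0.35
MIN_GENES = 100


def gene_cna_summary(cna_tumor: pd.DataFrame,
                     loss_thr: float = LOSS_THRESHOLD,
                     gain_thr: float = GAIN_THRESHOLD) -> pd.DataFrame:
    """Mean thresholded CNA per gene across tumors (missing cells ignored)
    and the loss/nc/gain bin. Genes with all-missing CNA are flagged
    excluded and carry no bin."""
    arr = cna_tumor.to_numpy(dtype=float)
    n_obs = np.sum(np.isfinite(arr), axis=1)
    with np.errstate(invalid="ignore"):
        mean_cna = np.where(
            n_obs > 0,
            np.nansum(np.nan_to_num(arr, nan=0.0), axis=1) / np.maximum(n_obs, 1),
            np.nan,
        )
    bin_ = np.full(len(cna_tumor), "nc", dtype=object)
    with np.errstate(invalid="ignore"):
        bin_[mean_cna < loss_thr] = "loss"
        bin_[mean_cna > gain_thr] = "gain"
    bin_[n_obs == 0] = "excluded"
    if (n_obs == 0).any():
        logger.warning("%d genes have all-missing CNA; excluded from region calling",
                       int((n_obs == 0).sum()))
    return pd.DataFrame({"mean_cna": mean_cna, "bin": bin_, "n_obs": n_obs},
                        index=cna_tumor.index)


@dataclass
class LossRegion:
    """A contiguous run of genes with recurrently reduced copy number."""

    cancer_code: str
    chromosome: str
    gene_span: list[str]
    start: int  # genomic span, 1-based inclusive
    end: int
    mean_cna: float
    rule: str = "primary"  # or "overlap_rescued"

    @property
    def n_genes(self) -> int:
        return len(self.gene_span)

    def contains_span(self, other: "LossRegion") -> bool:
        return (self.chromosome == other.chromosome
                and self.start <= other.start and other.end <= self.end)


def _maximal_windows(values: np.ndarray, loss_thr: float) -> list[tuple[int, int]]:
    """All containment-maximal windows [i, j] (inclusive) of `values` with
    mean <= loss_thr. `values` must already satisfy the tolerance bound."""
    n = len(values)
    if n == 0:
        return []
    # Q[k] = prefix_sum(k) - loss_thr * k; window [i, j] qualifies iff
    # Q[j+1] <= Q[i].
    q = np.concatenate([[0.0], np.cumsum(values - loss_thr)])
    eps = 1e-9  # boundary means ("-0.4 or less") qualify despite float noise
    windows: list[tuple[int, int]] = []
    best_end = -1
    for i in range(n):
        later = np.nonzero(q[i + 1:] <= q[i] + eps)[0]
        if later.size == 0:
            continue
        j = i + later[-1]  # largest j with Q[j+1] <= Q[i]
        if j > best_end:
            # not contained in any window started earlier
            windows.append((i, j))
            best_end = j
        # if j <= best_end the window is nested inside a previous one
    return windows


def _resolve_partial_overlaps(windows: list[tuple[int, int]],
                              values: np.ndarray) -> list[tuple[int, int]]:
    """Keep at most one of any pair of overlapping windows: more genes wins,
    ties broken by lower mean, then leftmost."""
    def sort_key(w):
        i, j = w
        return (-(j - i + 1), float(np.mean(values[i:j + 1])), i)

    kept: list[tuple[int, int]] = []
    for w in sorted(windows, key=sort_key):
        if all(w[1] < k[0] or k[1] < w[0] for k in kept):
            kept.append(w)
    return sorted(kept)


def call_loss_runs(summaries: pd.DataFrame,
                   annotations: dict[str, GeneAnnotation],
                   cancer_code: str = "",
                   loss_thr: float = LOSS_THRESHOLD,
                   tol: float = TOLERANCE) -> list[LossRegion]:
    """All maximal qualifying runs on position-ordered summaries, of any
    size (callers split them into primary regions and rescue candidates).

    `summaries` must be ordered by genomic position; rows carry mean_cna and
    the genes' annotations give chromosome/coordinates. Genes with bin
    'excluded' (all-missing CNA) break runs like out-of-tolerance genes.
    """
    _check_ordered(summaries, annotations)
    regions: list[LossRegion] = []
    for chrom, idx in _by_chromosome(summaries.index, annotations):
        vals = summaries.loc[idx, "mean_cna"].to_numpy(dtype=float)
        ok = np.isfinite(vals) & (vals < tol)
        # segments of consecutive tolerance-passing genes
        boundaries = np.flatnonzero(np.diff(np.concatenate([[0], ok.view(np.int8), [0]])))
        for s, e in zip(boundaries[::2], boundaries[1::2]):
            seg_vals = vals[s:e]
            wins = _maximal_windows(seg_vals, loss_thr)
            wins = _resolve_partial_overlaps(wins, seg_vals)
            for i, j in wins:
                genes = list(idx[s + i:s + j + 1])
                regions.append(LossRegion(
                    cancer_code=cancer_code,
                    chromosome=chrom,
                    gene_span=genes,
                    start=min(annotations[g].start for g in genes),
                    end=max(annotations[g].end for g in genes),
                    mean_cna=float(np.mean(seg_vals[i:j + 1])),
                ))
    return regions


def call_primary_regions(summaries: pd.DataFrame,
                         annotations: dict[str, GeneAnnotation],
                         cancer_code: str = "",
                         min_genes: int = MIN_GENES,
                         loss_thr: float = LOSS_THRESHOLD,
                         tol: float = TOLERANCE,
                         ) -> tuple[list[LossRegion], list[LossRegion]]:
    """Split maximal qualifying runs into primary regions (>= min_genes)
    and smaller rescue candidates. Returns (primary, candidates)."""
    runs = call_loss_runs(summaries, annotations, cancer_code, loss_thr, tol)
    primary = [r for r in runs if r.n_genes >= min_genes]
    candidates = [r for r in runs if r.n_genes < min_genes]
    logger.info("%s: %d primary regions, %d sub-threshold candidates",
                cancer_code or "cohort", len(primary), len(candidates))
    return primary, candidates


def rescue_overlapping_regions(candidates: list[LossRegion],
                               primary_by_cancer: dict[str, list[LossRegion]],
                               ) -> list[LossRegion]:
    """Promote a sub-minimum qualifying run if its genomic span is fully
    contained in a primary region called in a *different* cancer."""
    rescued = []
    for cand in candidates:
        for cancer, primaries in primary_by_cancer.items():
            if cancer == cand.cancer_code:
                continue
            if any(p.contains_span(cand) for p in primaries):
                rescued.append(LossRegion(
                    cancer_code=cand.cancer_code, chromosome=cand.chromosome,
                    gene_span=list(cand.gene_span), start=cand.start,
                    end=cand.end, mean_cna=cand.mean_cna,
                    rule="overlap_rescued",
                ))
                break
    return rescued


def region_overlap(a: LossRegion, b: LossRegion) -> tuple[int, float, set[str]]:
    """(shared_bp, containment fraction of the smaller span, shared genes)."""
    if a.chromosome != b.chromosome:
        return 0, 0.0, set()
    shared_bp = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    smaller = min(a.end - a.start + 1, b.end - b.start + 1)
    containment = shared_bp / smaller if smaller > 0 else 0.0
    shared_genes = set(a.gene_span) & set(b.gene_span)
    return shared_bp, containment, shared_genes


def _by_chromosome(genes: pd.Index, annotations: dict[str, GeneAnnotation]):
    """Yield (chromosome, gene sub-index) preserving input order."""
    current: list[str] = []
    chrom = None
    for g in genes:
        c = annotations[g].chromosome
        if c != chrom and current:
            yield chrom, pd.Index(current)
            current = []
        chrom = c
        current.append(g)
    if current:
        yield chrom, pd.Index(current)


def _check_ordered(summaries: pd.DataFrame,
                   annotations: dict[str, GeneAnnotation]) -> None:
    missing = [g for g in summaries.index if g not in annotations]
    if missing:
        raise KeyError(f"genes without annotation: {missing[:5]}")
    seen: set[str] = set()
    prev_chrom, prev_key = None, None
    for g in summaries.index:
        a = annotations[g]
        if a.chromosome != prev_chrom:
            if a.chromosome in seen:
                raise ValueError(
                    f"genes not grouped by chromosome (chromosome {a.chromosome} "
                    "appears twice)")
            seen.add(a.chromosome)
            prev_chrom, prev_key = a.chromosome, None
        key = (a.start, a.end)
        if prev_key is not None and key < prev_key:
            raise ValueError(f"genes not position-ordered at {g}")
        prev_key = key
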