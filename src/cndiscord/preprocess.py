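"""Sample matching, tumor/normal split, expression floor and gene ordering.

The expression and copy-number matrices for a cancer are trimmed to the
samples present in both, normals are removed from the copy-number side
(kept separately on the expression side for the tumor-vs-normal
comparison), genes whose mean log2 expression is not above the floor in
either tumor or normal are dropped, and the surviving genes are put in
chromosomal order using the probemap annotations.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneAnnotation, OmicsMatrix

logger = logging.getLogger(__name__)

# TCGA barcode: the sample-type code is the 4th dash-separated field.
_BARCODE_RE = re.compile(r"^TCGA-[^-]+-[^-]+-(\d{2})")

EXPRESSION_FLOOR = 2.0  # log2 units


@dataclass
class SampleTable:
    """sample_id -> (cancer_code, tissue_class in {tumor, normal})."""

    table: pd.DataFrame  # index sample_id, columns cancer_code, tissue_class

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample table")
        bad = set(self.table["tissue_class"]) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown tissue classes {bad}")

    def tumors(self) -> list[str]:
        t = self.table
        return list(t.index[t["tissue_class"] == "tumor"])

    def normals(self) -> list[str]:
        t = self.table
        return list(t.index[t["tissue_class"] == "normal"])


@dataclass
class AnalysisSet:
    """Matched tumor/normal views over one filtered, position-ordered gene list."""

    expr_tumor: pd.DataFrame
    expr_normal: pd.DataFrame
    cna_tumor: pd.DataFrame
    annotations: dict[str, GeneAnnotation]
    cancer_code: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.expr_tumor.index)


def classify_samples(sample_ids, cancer_code: str = "",
                     explicit: dict[str, str] | None = None) -> SampleTable:
    """Classify samples as tumor or normal.

    TCGA barcode sample-type codes 01-09 are tumors and 10-19 normals; an
    explicit {sample_id: class} mapping overrides the barcode convention
    (and is required for non-TCGA identifiers).
    """
    explicit = explicit or {}
    classes: dict[str, str] = {}
    unclassifiable: list[str] = []
    for sid in sample_ids:
        if sid in explicit:
            classes[sid] = explicit[sid]
            continue
        m = _BARCODE_RE.match(sid)
        if m:
            code = int(m.group(1))
            if 1 <= code <= 9:
                classes[sid] = "tumor"
                continue
            if 10 <= code <= 19:
                classes[sid] = "normal"
                continue
        unclassifiable.append(sid)
    if unclassifiable:
        raise ValueError(
            f"cannot classify samples (no barcode code, no explicit class): "
            f"{unclassifiable[:10]}"
        )
    df = pd.DataFrame(
        {"cancer_code": cancer_code,
         "tissue_class": [classes[s] for s in sample_ids]},
        index=pd.Index(list(sample_ids), name="sample_id"),
    )
    return SampleTable(df)


def match_and_split(expr: OmicsMatrix, cna: OmicsMatrix,
                    samples: SampleTable) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Trim to samples present in both matrices and split tumor from normal.

    Returns (expr_tumor, expr_normal, cna_tumor). Tumors must appear in both
    matrices; normal expression samples are kept even without CNA data,
    because they only serve as the comparison group for expression.
    """
    tumor_ids = [s for s in samples.tumors()
                 if s in expr.values.columns and s in cna.values.columns]
    normal_ids = [s for s in samples.normals() if s in expr.values.columns]
    if not tumor_ids:
        raise ValueError("no tumor samples shared between expression and CNA")
    logger.info("matched %d tumors (both matrices), %d expression normals",
                len(tumor_ids), len(normal_ids))
    return (expr.values[tumor_ids], expr.values[normal_ids],
            cna.values[tumor_ids])


def filter_expression_floor(expr_tumor: pd.DataFrame, expr_normal: pd.DataFrame,
                            floor: float = EXPRESSION_FLOOR) -> list[str]:
    """Keep a gene iff its mean log2 expression exceeds the floor in tumor
    OR in normal (means ignore missing cells)."""
    mean_t = expr_tumor.mean(axis=1, skipna=True)
    mean_n = expr_normal.mean(axis=1, skipna=True)
    keep = ((mean_t > floor) | (mean_n > floor)).reindex(expr_tumor.index)
    kept = list(expr_tumor.index[keep.fillna(False).to_numpy(dtype=bool)])
    logger.info("expression floor %.3g: kept %d / %d genes",
                floor, len(kept), len(expr_tumor))
    return kept


def order_by_position(genes, annotations: dict[str, GeneAnnotation]) -> list[str]:
    """Sort genes by (chromosome, start, end, gene_id); genes without an
    annotation are dropped with a warning."""
    annotated = [g for g in genes if g in annotations]
    n_dropped = len(list(genes)) - len(annotated)
    if n_dropped:
        logger.warning("%d genes lack annotations and were dropped", n_dropped)
    return sorted(
        annotated,
        key=lambda g: (annotations[g].chromosome, annotations[g].start,
                       annotations[g].end, g),
    )


def build_analysis_set(expr: OmicsMatrix, cna: OmicsMatrix,
                       samples: SampleTable,
                       annotations: list[GeneAnnotation] | dict[str, GeneAnnotation],
                       floor: float = EXPRESSION_FLOOR,
                       cancer_code: str = "") -> AnalysisSet:
    """Full preprocessing: match samples, apply the floor, order genes."""
    if not isinstance(annotations, dict):
        annotations = {a.gene_id: a for a in annotations}
    expr_t, expr_n, cna_t = match_and_split(expr, cna, samples)
    shared_genes = [g for g in expr_t.index if g in cna_t.index]
    expr_t, expr_n, cna_t = (expr_t.loc[shared_genes], expr_n.loc[shared_genes],
                             cna_t.loc[shared_genes])
    kept = filter_expression_floor(expr_t, expr_n, floor)
    ordered = order_by_position(kept, annotations)
    return AnalysisSet(
        expr_tumor=expr_t.loc[ordered],
        expr_normal=expr_n.loc[ordered],
        cna_tumor=cna_t.loc[ordered],
        annotations={g: annotations[g] for g in ordered},
        cancer_code=cancer_code,
    )
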