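"""Readers and writers for the pipeline's file formats.

Xena-style gene x sample TSV matrices (expression in log2 units, or
GISTIC2-thresholded copy-number calls in -2..+2), probemap tables placing
gene symbols on chromosomes, GMT gene-set files, plain gene lists, BED6
region export and CSV result tables.

Internal genomic coordinates are 1-based inclusive (the probemap
convention); only the BED writer converts to 0-based half-open.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATRIX_KINDS = ("expression_log2", "cna_thresholded")


class FormatError(ValueError):
    """Malformed input file (ragged rows, bad fields, out-of-range values)."""


class DuplicateIdError(FormatError):
    """Duplicate gene or sample identifier in a matrix file."""


@dataclass
class OmicsMatrix:
    """Gene x sample numeric matrix with a declared kind.

    values is a pandas DataFrame indexed by gene_id with sample_id columns.
    kind is "expression_log2" or "cna_thresholded"; thresholded CNA values
    must lie in [-2, +2] (NaN marks missing cells in either kind).
    """

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise DuplicateIdError(f"duplicate gene identifiers: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise DuplicateIdError(f"duplicate sample identifiers: {list(dups)[:5]}")
        if self.kind == "cna_thresholded":
            arr = self.values.to_numpy(dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -2 or finite.max() > 2):
                raise FormatError(
                    "thresholded CNA values must lie in [-2, +2]; "
                    f"found range [{finite.min()}, {finite.max()}]"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene placed on a chromosome; coordinates are 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chromosome:
            raise ValueError(f"{self.gene_id}: empty chromosome")
        if self.start > self.end:
            raise FormatError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_matrix_tsv(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a Xena-style TSV matrix: sample header row, gene-id first column.

    Empty cells become NaN (missing); ragged rows raise FormatError naming
    the offending line; duplicate gene rows raise DuplicateIdError.
    """
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if lineno == 1:
                ncol = len(fields)
                header = fields
                continue
            if len(fields) != ncol:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected {ncol}"
                )
            rows.append(fields)
    gene_ids = [r[0] for r in rows]
    body = np.full((len(rows), ncol - 1), np.nan)
    for i, r in enumerate(rows):
        for j, cell in enumerate(r[1:]):
            if cell != "":
                try:
                    body[i, j] = float(cell)
                except ValueError as e:
                    raise FormatError(
                        f"{path}: line {i + 2}, non-numeric cell {cell!r}"
                    ) from e
    df = pd.DataFrame(body, index=pd.Index(gene_ids, name="gene_id"),
                      columns=header[1:])
    mat = OmicsMatrix(values=df, kind=kind)
    logger.info("read %s: %d genes x %d samples", path, *mat.shape)
    return mat


def write_matrix_tsv(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix back to Xena-style TSV (NaN as empty cell)."""
    df = matrix.values
    with _open_text(path, "wt") as fh:
        fh.write("sample\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in df.iterrows():
            cells = ["" if not np.isfinite(v) else f"{v:.6f}" for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


def read_probemap(path: str | Path) -> list[GeneAnnotation]:
    """Read a probemap TSV (id, gene, chromosome, start, end, strand).

    One annotation per gene symbol. A symbol mapping to more than one
    chromosome has no single position along which regions could be ordered,
    so it is dropped entirely and logged.
    """
    per_gene: dict[str, list[GeneAnnotation]] = {}
    n_rows = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"id", "#id", "probe"}:
                continue
            if len(fields) < 5:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >=5"
                )
            gene = fields[1]
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "unknown"
            ann = GeneAnnotation(
                gene_id=gene,
                chromosome=fields[2],
                start=int(fields[3]),
                end=int(fields[4]),
                strand=strand,
            )
            per_gene.setdefault(gene, []).append(ann)
            n_rows += 1
    out: list[GeneAnnotation] = []
    n_ambiguous = 0
    for gene, anns in per_gene.items():
        chroms = {a.chromosome for a in anns}
        if len(chroms) > 1:
            n_ambiguous += 1
            logger.warning(
                "gene %s maps to multiple chromosomes %s; dropped", gene, sorted(chroms)
            )
            continue
        # multiple loci on one chromosome: widest span wins
        ann = anns[0]
        if len(anns) > 1:
            start = min(a.start for a in anns)
            end = max(a.end for a in anns)
            ann = GeneAnnotation(gene, ann.chromosome, start, end, ann.strand)
        out.append(ann)
    if n_rows == 0:
        logger.warning("probemap %s is empty", path)
    logger.info(
        "probemap %s: %d rows -> %d genes (%d ambiguous dropped)",
        path, n_rows, len(out), n_ambiguous,
    )
    return out


def write_probemap(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("id\tgene\tchrom\tchromStart\tchromEnd\tstrand\n")
        for a in annotations:
            fh.write(
                f"{a.gene_id}\t{a.gene_id}\t{a.chromosome}\t{a.start}\t{a.end}\t"
                f"{a.strand if a.strand in '+-' else '.'}\n"
            )


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description, then members, tab-separated.

    Duplicate members within a line are deduplicated with a warning; a line
    whose member list is empty after deduplication is rejected.
    """
    sets: list[GeneSet] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >=3"
                )
            name, desc = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            if len(set(members)) < len(members):
                logger.warning(
                    "gene set %s (line %d): duplicate members deduplicated",
                    name, lineno,
                )
            if not members:
                raise FormatError(
                    f"{path}: line {lineno} ({name}) has no members"
                )
            sets.append(GeneSet(name=name, description=desc,
                                members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for s in sets:
            fh.write(s.name + "\t" + s.description + "\t"
                     + "\t".join(sorted(s.members)) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a plain one-gene-per-line list (e.g. DepMap common essentials)."""
    with _open_text(path) as fh:
        genes = [line.strip() for line in fh]
    return frozenset(g for g in genes if g and not g.startswith("#"))


def write_regions_bed(regions: Sequence, path: str | Path) -> None:
    """Export loss regions as BED6: 0-based half-open, name = cancer:rule,
    score = round(-100 * mean CNA)."""
    with _open_text(path, "wt") as fh:
        fh.write('track name="loss_regions"\n')
        for r in regions:
            score = int(round(-100.0 * r.mean_cna))
            fh.write(
                f"{r.chromosome}\t{r.start - 1}\t{r.end}\t"
                f"{r.cancer_code}:{r.rule}\t{score}\t.\n"
            )
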