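"""Synthetic TCGA-like cohorts with planted ground truth.

The generator emulates the structure the pipeline is built to detect:
paired expression / thresholded-CNA matrices over genes laid out on
chromosomes, tumor and matched-normal samples with TCGA-style barcodes,
planted arm-scale loss (or gain) regions, a linear dosage effect of copy
number on log2 expression, and a planted minority of discordant genes that
are upregulated in tumors independently of their copy-number loss.

Copy-number events are arm-level by construction: each planted region
draws, per tumor, a single whole-region call (-1 for loss regions, +1 for
gain), so every gene in a region shares the tumor's call, as
GISTIC-thresholded calls do for arm losses. By default the number of
carrier tumors is round(fraction * n_tumors) exactly, so the per-gene mean
CNA hits the configured target; set sample_loss_tumors=True for per-tumor
Bernoulli sampling instead.

Expression model (log2 scale), per gene g and sample s:

    x[g, s] = baseline[g] + dosage_slope * cna[g, s] + effect[g] * tumor[s]
              + N(0, noise_sd)

except that planted differentially-expressed genes (discordant, up, down)
ignore the dosage term entirely: they model the output of copy-number
independent transcriptional programs. The discordant genes are the members
of the planted up-program that happen to sit inside loss regions — which is
exactly what makes them discordant; a few up-program genes are placed in
the gain region so the program spans all three copy-number bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, OmicsMatrix
from .preprocess import SampleTable, classify_samples

GENE_SPACING = 10_000  # bp between synthetic gene starts
GENE_LENGTH = 1_000


@dataclass
class PlantedRegion:
    """A contiguous block of genes on one chromosome carrying a shared
    copy-number event; negative mean_cna_target plants loss, positive
    plants gain."""

    chromosome: str
    first_gene_index: int  # within the chromosome, 0-based inclusive
    last_gene_index: int
    mean_cna_target: float

    def __post_init__(self) -> None:
        if self.first_gene_index > self.last_gene_index:
            raise ValueError("empty planted region")
        if not 0 < abs(self.mean_cna_target) <= 1:
            raise ValueError("mean_cna_target must be in (0, 1] in magnitude "
                             "(single-copy events)")


@dataclass
class TruthConfig:
    """Study conditions for a synthetic cohort."""

    regions: list[PlantedRegion] = field(default_factory=list)
    n_discordant_per_region: int = 5
    discordant_effect: float = 1.5   # log2 tumor upshift of discordant genes
    n_up_genes: int = 60             # planted up-program genes outside loss regions
    n_up_in_gain: int = 5            # of which this many sit in gain regions
    n_down_genes: int = 60
    up_effect: float = 1.5
    down_effect: float = -1.5
    dosage_slope: float = 1.0        # log2 expression change per CNA unit
    noise_sd: float = 0.5            # per-cell log2 noise
    baseline_range: tuple[float, float] = (5.0, 10.0)
    low_expr_fraction: float = 0.05  # genes planted below the expression floor
    low_expr_range: tuple[float, float] = (0.0, 1.5)
    sample_loss_tumors: bool = False  # Bernoulli carriers instead of exact count

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class CohortTruth:
    """Planted ground truth, for scoring recovery."""

    loss_regions: list[PlantedRegion]
    gain_regions: list[PlantedRegion]
    region_genes: dict[str, list[str]]     # region key -> gene ids
    discordant_genes: frozenset[str]
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    low_expr_genes: frozenset[str]
    dosage_slope: float
    noise_sd: float
    seed: int

    @property
    def program_genes(self) -> frozenset[str]:
        """The planted copy-number-independent up-program: the discordant
        genes plus the up genes outside loss regions."""
        return self.discordant_genes | self.up_genes


def default_truth_config(n_genes: int = 2000, n_chromosomes: int = 5,
                         region_size: int = 150,
                         mean_cna_target: float = -0.5) -> TruthConfig:
    """Two planted loss regions and one gain region on separate
    chromosomes, sized for the standard 2000-gene / 5-chromosome cohort."""
    per_chrom = n_genes // n_chromosomes
    if region_size > per_chrom:
        raise ValueError("region does not fit on a chromosome")
    offset = (per_chrom - region_size) // 2
    span = (offset, offset + region_size - 1)
    regions = [PlantedRegion("chr1", *span, mean_cna_target)]
    if n_chromosomes >= 2:
        regions.append(PlantedRegion("chr2", *span, mean_cna_target))
    if n_chromosomes >= 3:
        regions.append(PlantedRegion("chr3", *span, abs(mean_cna_target)))
    return TruthConfig(regions=regions)


def _make_annotations(n_genes: int, n_chromosomes: int
                      ) -> tuple[list[str], dict[str, GeneAnnotation], dict[str, list[int]]]:
    per_chrom = n_genes // n_chromosomes
    extras = n_genes - per_chrom * n_chromosomes
    gene_ids, annotations = [], {}
    chrom_gene_rows: dict[str, list[int]] = {}
    row = 0
    for c in range(n_chromosomes):
        chrom = f"chr{c + 1}"
        size = per_chrom + (1 if c < extras else 0)
        chrom_gene_rows[chrom] = []
        for i in range(size):
            gid = f"G{row:05d}"
            start = 1 + i * GENE_SPACING
            annotations[gid] = GeneAnnotation(gid, chrom, start,
                                              start + GENE_LENGTH - 1, "+")
            gene_ids.append(gid)
            chrom_gene_rows[chrom].append(row)
            row += 1
    return gene_ids, annotations, chrom_gene_rows


def generate_cohort(n_genes: int = 2000, n_chromosomes: int = 5,
                    n_tumors: int = 100, n_normals: int = 20,
                    truth_config: TruthConfig | None = None,
                    seed: int = 0,
                    ) -> tuple[OmicsMatrix, OmicsMatrix, dict[str, GeneAnnotation],
                               SampleTable, CohortTruth]:
    """Generate one cancer's paired matrices plus planted truth.

    Returns (expr, cna, annotations, sample_table, truth). Normals are
    copy-neutral everywhere; deterministic for a fixed seed.
    """
    if n_tumors < 2 or n_normals < 2:
        raise ValueError("need at least two tumors and two normals")
    cfg = truth_config if truth_config is not None else default_truth_config(
        n_genes, n_chromosomes)
    rng = np.random.default_rng(seed)

    gene_ids, annotations, chrom_rows = _make_annotations(n_genes, n_chromosomes)
    tumor_ids = [f"TCGA-SY-T{i:03d}-01" for i in range(n_tumors)]
    normal_ids = [f"TCGA-SY-N{i:03d}-11" for i in range(n_normals)]
    samples = classify_samples(tumor_ids + normal_ids, cancer_code="SYN")

    # --- copy number ------------------------------------------------------
    cna = np.zeros((n_genes, n_tumors + n_normals))
    region_genes: dict[str, list[str]] = {}
    claimed: dict[str, set[int]] = {}
    for reg in cfg.regions:
        if reg.chromosome not in chrom_rows:
            raise ValueError(f"unknown chromosome {reg.chromosome}")
        rows = chrom_rows[reg.chromosome]
        if reg.last_gene_index >= len(rows):
            raise ValueError(f"planted region exceeds {reg.chromosome} "
                             f"({len(rows)} genes)")
        span = set(range(reg.first_gene_index, reg.last_gene_index + 1))
        if span & claimed.get(reg.chromosome, set()):
            raise ValueError(f"planted regions overlap on {reg.chromosome}")
        claimed.setdefault(reg.chromosome, set()).update(span)

        call = -1 if reg.mean_cna_target < 0 else 1
        frac = abs(reg.mean_cna_target)
        if cfg.sample_loss_tumors:
            carriers = np.flatnonzero(rng.random(n_tumors) < frac)
        else:
            carriers = rng.choice(n_tumors, size=round(frac * n_tumors),
                                  replace=False)
        reg_rows = [rows[i] for i in sorted(span)]
        for r in reg_rows:
            cna[r, carriers] = call
        key = f"{reg.chromosome}:{reg.first_gene_index}-{reg.last_gene_index}"
        region_genes[key] = [gene_ids[r] for r in reg_rows]

    # --- planted gene effects --------------------------------------------
    loss_keys = [k for k, reg in zip(region_genes, cfg.regions)
                 if reg.mean_cna_target < 0]
    gain_keys = [k for k in region_genes if k not in loss_keys]
    discordant: list[str] = []
    for k in loss_keys:
        picks = rng.choice(len(region_genes[k]),
                           size=min(cfg.n_discordant_per_region,
                                    len(region_genes[k])), replace=False)
        discordant.extend(region_genes[k][i] for i in sorted(picks))

    # the up-program spans the copy-number bins: a few members in gain
    # regions, the rest (with the down genes) outside all planted regions
    in_regions = {g for genes in region_genes.values() for g in genes}
    gain_pool = [g for k in gain_keys for g in region_genes[k]]
    n_in_gain = min(cfg.n_up_in_gain, cfg.n_up_genes, len(gain_pool))
    gain_picks = rng.choice(len(gain_pool), size=n_in_gain, replace=False)
    up_genes = [gain_pool[i] for i in sorted(gain_picks)]

    outside = [g for g in gene_ids if g not in in_regions]
    n_de = (cfg.n_up_genes - n_in_gain) + cfg.n_down_genes
    de_picks = rng.choice(len(outside), size=min(n_de, len(outside)),
                          replace=False)
    up_genes += [outside[i] for i in de_picks[:cfg.n_up_genes - n_in_gain]]
    down_genes = [outside[i] for i in de_picks[cfg.n_up_genes - n_in_gain:]]

    n_low = int(round(cfg.low_expr_fraction * n_genes))
    special = set(discordant) | set(up_genes) | set(down_genes) | in_regions
    low_pool = [g for g in gene_ids if g not in special]
    low_picks = rng.choice(len(low_pool), size=min(n_low, len(low_pool)),
                           replace=False)
    low_genes = [low_pool[i] for i in low_picks]

    # --- expression -------------------------------------------------------
    row_of = {g: i for i, g in enumerate(gene_ids)}
    baseline = rng.uniform(*cfg.baseline_range, size=n_genes)
    for g in low_genes:
        baseline[row_of[g]] = rng.uniform(*cfg.low_expr_range)

    effect = np.zeros(n_genes)
    for g in discordant:
        effect[row_of[g]] = cfg.discordant_effect
    for g in up_genes:
        effect[row_of[g]] = cfg.up_effect
    for g in down_genes:
        effect[row_of[g]] = cfg.down_effect

    is_tumor = np.concatenate([np.ones(n_tumors), np.zeros(n_normals)])
    dosage = cfg.dosage_slope * cna
    # planted program genes are copy-number independent: no dosage term
    program_rows = [row_of[g] for g in (*discordant, *up_genes, *down_genes)]
    dosage[program_rows, :] = 0.0

    expr = (baseline[:, None] + dosage + effect[:, None] * is_tumor[None, :]
            + rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_tumors + n_normals)))

    all_ids = tumor_ids + normal_ids
    expr_m = OmicsMatrix(pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                                      columns=all_ids), kind="expression_log2")
    cna_m = OmicsMatrix(pd.DataFrame(cna, index=pd.Index(gene_ids, name="gene_id"),
                                     columns=all_ids), kind="cna_thresholded")
    truth = CohortTruth(
        loss_regions=[r for r in cfg.regions if r.mean_cna_target < 0],
        gain_regions=[r for r in cfg.regions if r.mean_cna_target > 0],
        region_genes=region_genes,
        discordant_genes=frozenset(discordant),
        up_genes=frozenset(up_genes),
        down_genes=frozenset(down_genes),
        low_expr_genes=frozenset(low_genes),
        dosage_slope=cfg.dosage_slope,
        noise_sd=cfg.noise_sd,
        seed=seed,
    )
    return expr_m, cna_m, annotations, samples, truth


@dataclass
class TagExperiment:
    """Ct readings for a tag-mix experiment plus the time-zero reference."""

    ct: pd.DataFrame            # tumors x tags
    reference_ct: pd.Series     # per tag
    true_proportions: pd.DataFrame


def generate_tag_experiment(true_proportions_per_tumor,
                            ct_noise_sd: float = 0.0, seed: int = 0,
                            reference_proportions=None,
                            base_ct: float = 20.0) -> TagExperiment:
    """Ct table consistent with the 2^dCt quantification model.

    true_proportions_per_tumor: tumors x tags table (rows sum to 1).
    Each tag's Ct satisfies Ct_tumor - Ct_reference =
    -log2(proportion / reference_proportion) + noise; a zero proportion is
    emitted as not-detected (NaN Ct).
    """
    props = pd.DataFrame(true_proportions_per_tumor, dtype=float)
    if not np.allclose(props.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("per-tumor proportions must sum to 1")
    rng = np.random.default_rng(seed)
    tags = list(props.columns)
    if reference_proportions is None:
        ref_p = pd.Series(1.0 / len(tags), index=tags)
    else:
        ref_p = pd.Series(reference_proportions, index=tags, dtype=float)
    reference_ct = pd.Series(base_ct, index=tags)

    with np.errstate(divide="ignore"):
        dct = -np.log2(props.to_numpy() / ref_p.to_numpy()[None, :])
    noise = rng.normal(0.0, ct_noise_sd, size=dct.shape) if ct_noise_sd > 0 else 0.0
    ct = base_ct + dct + noise
    ct = np.where(props.to_numpy() == 0.0, np.nan, ct)  # not-detected
    return TagExperiment(
        ct=pd.DataFrame(ct, index=props.index, columns=tags),
        reference_ct=reference_ct,
        true_proportions=props,
    )
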