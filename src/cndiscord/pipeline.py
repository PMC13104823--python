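"""Orchestration: per-cancer stages, cross-cancer integration, manifests.

Per cancer: preprocess -> differential expression -> copy-number summary ->
region calling. Across cancers (only after every cancer finished, because
rescue needs all primary regions): overlap rescue of small runs, discordant
gene lists, sharing histogram, and pairwise hypergeometric overlap tests
restricted to shared loss regions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cna_regions import (GAIN_THRESHOLD, LOSS_THRESHOLD, MIN_GENES, TOLERANCE,
                          LossRegion, call_primary_regions, gene_cna_summary,
                          region_overlap, rescue_overlapping_regions)
from .concordance import (bin_tier_proportions, discordant_genes,
                          pairwise_overlap_test, sharing_histogram)
from .diffexpr import (RELAXED_CUTOFF, STRICT_CUTOFF, classify_tiers,
                       differential_expression, is_up)
from .io_formats import read_matrix_tsv, read_probemap, write_regions_bed
from .preprocess import (EXPRESSION_FLOOR, AnalysisSet, build_analysis_set,
                         classify_samples)

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    floor: float = EXPRESSION_FLOOR
    loss_thr: float = LOSS_THRESHOLD
    gain_thr: float = GAIN_THRESHOLD
    tol: float = TOLERANCE
    min_genes: int = MIN_GENES
    strict: tuple[float, float] = STRICT_CUTOFF
    relaxed: tuple[float, float] = RELAXED_CUTOFF
    min_list: int = 15
    discordant_tier: str = "strict"
    overlap_tier: str = "relaxed"

    def validate(self) -> None:
        if not (self.loss_thr < self.tol < 0 < self.gain_thr):
            raise ValueError(
                f"thresholds must satisfy loss_thr < tol < 0 < gain_thr, got "
                f"{self.loss_thr}, {self.tol}, {self.gain_thr}")
        if self.min_genes < 1 or self.min_list < 1:
            raise ValueError("min_genes and min_list must be positive")


@dataclass
class RunConfig:
    cancers: dict[str, dict[str, str]]  # name -> {expr: path, cna: path}
    probemap: str
    out_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    sample_classes: dict[str, str] | None = None  # overrides barcode rule
    seed: int = 0

    def validate(self) -> None:
        if not self.cancers:
            raise ValueError("at least one cancer must be configured")
        self.thresholds.validate()
        missing = [p for c in self.cancers.values() for p in c.values()
                   if not Path(p).exists()]
        if not Path(self.probemap).exists():
            missing.append(self.probemap)
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in raw.get("thresholds", {}).items()})
        return cls(cancers=raw["cancers"], probemap=raw["probemap"],
                   out_dir=raw["out_dir"], thresholds=thr,
                   sample_classes=raw.get("sample_classes"),
                   seed=raw.get("seed", 0))


@dataclass
class CancerResult:
    cancer_code: str
    analysis_set: AnalysisSet
    records: pd.DataFrame          # tiered differential expression
    summaries: pd.DataFrame        # per-gene CNA mean + bin
    primary_regions: list[LossRegion]
    candidates: list[LossRegion]
    rescued_regions: list[LossRegion] = field(default_factory=list)

    @property
    def regions(self) -> list[LossRegion]:
        return self.primary_regions + self.rescued_regions


def analyze_cancer(aset: AnalysisSet, thresholds: Thresholds | None = None
                   ) -> CancerResult:
    """Run the per-cancer stages on a preprocessed analysis set."""
    thr = thresholds or Thresholds()
    thr.validate()
    records = classify_tiers(
        differential_expression(aset.expr_tumor, aset.expr_normal),
        strict=thr.strict, relaxed=thr.relaxed)
    summaries = gene_cna_summary(aset.cna_tumor, loss_thr=thr.loss_thr,
                                 gain_thr=thr.gain_thr)
    usable = summaries[summaries["bin"] != "excluded"]
    primary, candidates = call_primary_regions(
        usable, aset.annotations, cancer_code=aset.cancer_code,
        min_genes=thr.min_genes, loss_thr=thr.loss_thr, tol=thr.tol)
    return CancerResult(aset.cancer_code, aset, records, summaries,
                        primary, candidates)


def integrate_cancers(results: dict[str, CancerResult],
                      thresholds: Thresholds | None = None) -> dict:
    """Cross-cancer stages: rescue, discordant lists, sharing, overlaps."""
    thr = thresholds or Thresholds()
    primary_by_cancer = {c: r.primary_regions for c, r in results.items()}
    for r in results.values():
        r.rescued_regions = rescue_overlapping_regions(
            r.candidates, primary_by_cancer)

    discordant: dict[str, pd.DataFrame] = {}
    per_region: dict[str, pd.DataFrame] = {}
    for c, r in results.items():
        genes, regions_tbl = discordant_genes(r.records, r.regions,
                                              tier=thr.discordant_tier)
        discordant[c] = genes
        per_region[c] = regions_tbl

    out: dict = {"discordant": discordant, "per_region": per_region}
    if len(results) >= 2:
        lists = {c: set(d.index) for c, d in discordant.items()}
        annotations: dict = {}
        for r in results.values():
            annotations.update(r.analysis_set.annotations)
        hist, per_gene = sharing_histogram(lists, annotations)
        out["sharing_histogram"] = hist
        out["sharing_per_gene"] = per_gene
        out["pairwise_overlaps"] = pairwise_region_overlap_tests(
            results, tier=thr.overlap_tier, min_list=thr.min_list)
    return out


def pairwise_region_overlap_tests(results: dict[str, CancerResult],
                                  tier: str = "relaxed",
                                  min_list: int = 15) -> pd.DataFrame:
    """For each pair of cancers sharing a loss region, test whether their
    upregulated genes inside the shared region overlap more than chance.

    Universe = expression-floor-passing genes analyzed in both cancers and
    lying inside both cancers' regions; lists = those universe genes
    upregulated at `tier` in each cancer. Pairs where either list is below
    min_list are not tested (reported with NaN p).
    """
    rows = []
    cancers = sorted(results)
    for i, ca in enumerate(cancers):
        for cb in cancers[i + 1:]:
            ra, rb = results[ca], results[cb]
            for reg_a in ra.regions:
                for reg_b in rb.regions:
                    shared_bp, containment, _ = region_overlap(reg_a, reg_b)
                    if shared_bp == 0:
                        continue
                    genes_a = set(reg_a.gene_span) & set(ra.records.index)
                    genes_b = set(reg_b.gene_span) & set(rb.records.index)
                    universe = genes_a & genes_b
                    if not universe:
                        continue
                    up_a = universe & set(ra.records.index[is_up(ra.records, tier)])
                    up_b = universe & set(rb.records.index[is_up(rb.records, tier)])
                    test = pairwise_overlap_test(up_a, up_b, universe,
                                                 min_list=min_list,
                                                 cancer_a=ca, cancer_b=cb)
                    rows.append({
                        "cancer_a": ca, "cancer_b": cb,
                        "chromosome": reg_a.chromosome,
                        "region_a": f"{reg_a.start}-{reg_a.end}",
                        "region_b": f"{reg_b.start}-{reg_b.end}",
                        "n_universe": len(universe),
                        "n_up_a": len(up_a), "n_up_b": len(up_b),
                        "n_shared": len(up_a & up_b),
                        "containment": containment,
                        "p_value": test.p_value if test else np.nan,
                        "tested": test is not None,
                    })
    cols = ["cancer_a", "cancer_b", "chromosome", "region_a", "region_b",
            "n_universe", "n_up_a", "n_up_b", "n_shared", "containment",
            "p_value", "tested"]
    return pd.DataFrame(rows, columns=cols)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps({
        "cancers": config.cancers, "probemap": config.probemap,
        "thresholds": vars(config.thresholds) | {}, "seed": config.seed,
    }, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """File-based end-to-end run: read inputs, run every stage, write CSVs,
    BED exports and a manifest. Returns the in-memory results bundle."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotations = {a.gene_id: a for a in read_probemap(config.probemap)}

    results: dict[str, CancerResult] = {}
    manifest: dict = {"version": __version__, "config_hash": _config_hash(config),
                      "seed": config.seed, "stages": {}, "libraries": {
                          "numpy": np.__version__, "pandas": pd.__version__}}
    for cancer, paths in config.cancers.items():
        try:
            expr = read_matrix_tsv(paths["expr"], kind="expression_log2")
            cna = read_matrix_tsv(paths["cna"], kind="cna_thresholded")
            samples = classify_samples(expr.sample_ids, cancer_code=cancer,
                                       explicit=config.sample_classes)
            aset = build_analysis_set(expr, cna, samples, annotations,
                                      floor=config.thresholds.floor,
                                      cancer_code=cancer)
            results[cancer] = analyze_cancer(aset, config.thresholds)
        except Exception as e:
            raise RuntimeError(f"stage failed for cancer {cancer}: {e}") from e
        r = results[cancer]
        manifest["stages"][cancer] = {
            "n_tumors": r.analysis_set.expr_tumor.shape[1],
            "n_normals": r.analysis_set.expr_normal.shape[1],
            "n_genes": len(r.analysis_set.genes),
            "n_primary_regions": len(r.primary_regions),
            "n_candidates": len(r.candidates),
        }

    cross = integrate_cancers(results, config.thresholds)

    for cancer, r in results.items():
        r.records.rename_axis("gene_id").to_csv(out_dir / f"{cancer}_diffexpr.csv")
        r.summaries.rename_axis("gene_id").to_csv(out_dir / f"{cancer}_cna_summary.csv")
        bin_tier_proportions(r.records, r.summaries).to_csv(
            out_dir / f"{cancer}_bin_proportions.csv")
        write_regions_bed(r.regions, out_dir / f"{cancer}_regions.bed")
        cross["discordant"][cancer].to_csv(out_dir / f"{cancer}_discordant.csv")
        cross["per_region"][cancer].to_csv(out_dir / f"{cancer}_regions.csv")
        manifest["stages"][cancer]["n_rescued"] = len(r.rescued_regions)
        manifest["stages"][cancer]["n_discordant"] = len(cross["discordant"][cancer])
    if "sharing_histogram" in cross:
        cross["sharing_histogram"].rename("n_genes").to_csv(
            out_dir / "sharing_histogram.csv")
        cross["sharing_per_gene"].to_csv(out_dir / "sharing_per_gene.csv")
        cross["pairwise_overlaps"].to_csv(out_dir / "pairwise_overlaps.csv",
                                          index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %d cancers -> %s", len(results), out_dir)
    return {"results": results, "cross": cross, "manifest": manifest}
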