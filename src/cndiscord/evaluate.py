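"""Scoring pipeline output against a synthetic cohort's planted truth."""

from __future__ import annotations

import numpy as np

from .concordance import discordant_genes
from .pipeline import CancerResult
from .synthetic_data import CohortTruth


def score_region_recovery(result: CancerResult, truth: CohortTruth) -> dict:
    """Compare called primary regions with the planted loss regions.

    A planted region counts as exactly recovered when some called region's
    gene span equals the planted one restricted to analyzed (floor-passing)
    genes.
    """
    analyzed = set(result.records.index)
    planted = []
    for reg in truth.loss_regions:
        key = f"{reg.chromosome}:{reg.first_gene_index}-{reg.last_gene_index}"
        planted.append([g for g in truth.region_genes[key] if g in analyzed])
    called = [list(r.gene_span) for r in result.primary_regions]
    n_exact = sum(1 for span in planted if span in called)
    extra = len(called) - sum(1 for span in called if span in planted)
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "n_exact": n_exact,
        "n_spurious": extra,
        "all_exact": n_exact == len(planted) and extra == 0,
    }


def score_discordant_recovery(result: CancerResult, truth: CohortTruth,
                              tier: str = "strict") -> dict:
    """Sensitivity and FDR of the discordant-gene caller on planted truth."""
    called, _ = discordant_genes(result.records, result.regions, tier=tier)
    called_set = set(called.index)
    planted = set(truth.discordant_genes)
    tp = len(called_set & planted)
    sensitivity = tp / len(planted) if planted else np.nan
    fdr = (len(called_set) - tp) / len(called_set) if called_set else 0.0
    return {"n_called": len(called_set), "n_planted": len(planted),
            "sensitivity": sensitivity, "fdr": fdr}
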