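import numpy as np
import pandas as pd
import pytest

from cndiscord.preprocess import build_analysis_set
from cndiscord.synthetic_data import (TruthConfig, default_truth_config,
                                      generate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """One standard synthetic cancer: 2000 genes / 5 chromosomes, two
    planted loss regions and one gain region, 100 tumors + 20 normals."""
    return generate_cohort(n_genes=2000, n_chromosomes=5, n_tumors=100,
                           n_normals=20, seed=11)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    expr, cna, annotations, samples, truth = small_cohort
    aset = build_analysis_set(expr, cna, samples, annotations,
                              cancer_code="SYN")
    return aset, truth


@pytest.fixture(scope="session")
def small_result(small_analysis):
    from cndiscord.pipeline import analyze_cancer
    aset, truth = small_analysis
    return analyze_cancer(aset), aset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
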