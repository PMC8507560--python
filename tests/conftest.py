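import logging

import numpy as np
import pandas as pd
import pytest

from telorisk.synthetic import CohortConfig, PlantedOutlier, _group_rates, generate_cohort

# silence expected per-sample warnings (degenerate tables, zero coverage) in bulk runs
logging.getLogger("telorisk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """One full default cohort, shared across read-only tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def three_gene_config(seed: int) -> CohortConfig:
    """Cohort config with exactly three planted genes at the screening rates."""
    planted = [PlantedOutlier(g, "high", _group_rates(0.30)) for g in ("TERT", "NOP10", "FBXO4")]
    return CohortConfig(seed=seed, planted=planted)


@pytest.fixture()
def small_groups():
    n_met, n_ref = 20, 15
    labels = ["metastatic"] * n_met + ["nonmetastatic_long"] * n_ref
    return pd.Series(labels, index=[f"S{i:03d}" for i in range(len(labels))])
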