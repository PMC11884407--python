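import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import suppressor_screen as sx

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """24-tumor cohort with one planted suppressor at effect_r=-0.8."""
    truth = sx.default_truth(n_null=20, effect_r=-0.8)
    cohort, truth = sx.generate_cell_cohort(truth=truth, seed=1)
    lognorm = sx.normalize_log(cohort.counts)
    return cohort, truth, lognorm


@pytest.fixture(scope="session")
def small_cohort():
    """6-tumor cohort, reduced subsets, for fast structural tests."""
    sizes = {"tumor": 15, "NK": 10, "CD8T": 10, "gdT": 8, "myeloid": 8}
    truth = sx.default_truth(n_null=5, effect_r=-0.8)
    cohort, truth = sx.generate_cell_cohort(
        n_tumors=6, subset_sizes=sizes, n_genes=120, truth=truth, seed=42
    )
    lognorm = sx.normalize_log(cohort.counts)
    return cohort, truth, lognorm


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
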