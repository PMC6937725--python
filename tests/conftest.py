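import numpy as np
import pytest

from stromaflow import CohortConfig, PanelSpec, simulate_cohort
from stromaflow.pipeline import gate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, small enough for fast unit tests."""
    cfg = CohortConfig(n_patients=6, n_events_per_sample=1200, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def gated_cohort(small_cohort):
    return small_cohort, gate_cohort(small_cohort, PanelSpec())


@pytest.fixture(scope="session")
def paired_cohort():
    """Fully paired two-site cohort for intrapatient statistics."""
    cfg = CohortConfig(n_patients=8, paired_fraction=1.0,
                       n_events_per_sample=1200, seed=7,
                       effect_sizes={}, pd1_high_cd8_shift=0.0)
    return simulate_cohort(cfg)
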