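import numpy as np
import pytest

from mwppg import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-subject default-condition cohort shared across tests."""
    cfg = SimConfig(n_subjects=10, seed=42)
    records, labels = simulate_cohort(cfg)
    return cfg, records, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
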