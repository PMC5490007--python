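import numpy as np
import pytest

from chromamp.synthetic_data import build_default_config, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-genome cohort with planted truth, shared across tests."""
    cfg = build_default_config(n_samples=12, seed=42)
    data, truth = simulate_cohort(cfg)
    return cfg, data, truth
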