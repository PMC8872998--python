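import numpy as np
import pytest

from slopekit import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort shared by read-only tests."""
    cfg = synthetic.CohortConfig(
        n_subjects=30, n_probes=60, n_causal=8, target_r2=0.25, seed=7
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
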