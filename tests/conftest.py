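import numpy as np
import pytest

from leidyn.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy 4-state cohort shared by recovery-style tests."""
    cfg = CohortConfig(
        n_regions=30, n_volumes=300, n_per_group=3, k_true=4, noise_sd=0.1, seed=7
    )
    recs, tls, truth = generate_cohort(cfg)
    return cfg, recs, tls, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
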