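import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=25)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small planted-effect cohort in fast connectivity mode."""
    from ccgrad import CohortConfig, build_cohort

    cfg = CohortConfig(mode="connectivity", n_per_cell=6, seed=11)
    return build_cohort(cfg)


@pytest.fixture(scope="session")
def chain_affinity():
    """Gaussian-kernel affinity of a 1-D chain, n=30."""
    i = np.arange(30)
    return np.exp(-((i[:, None] - i[None, :]) ** 2) / 2.0)
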