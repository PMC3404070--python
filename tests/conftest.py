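import numpy as np
import pytest
from hypothesis import settings

from sfskit.saf import saf_from_log_triples
from sfskit.simulate import SimConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset shared by read-level tests."""
    cfg = SimConfig(k=5, n_sites=300, mean_depth=4.0, error_rate=0.01,
                    p_var=0.3, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture
def random_saf_table(rng):
    """A small random SAF table (k=3, 40 sites)."""
    return saf_from_log_triples(np.log(rng.random((40, 3, 3))))
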