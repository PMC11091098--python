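import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from vampseq.config import small_config
from vampseq.simulate import simulate_library


@pytest.fixture(scope="session")
def small_cfg():
    return small_config(seed=11)


@pytest.fixture(scope="session")
def small_library(small_cfg):
    """One small simulated library shared across tests (read-only)."""
    return simulate_library(small_cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def toy_protein():
    return "MKVLITGAGH"  # 10 residues, CDS of 30 nt
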