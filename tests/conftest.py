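import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from floratx.simulate import SimulationConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def default_truth():
    """Moderate-size truth set under default study conditions."""
    cfg = SimulationConfig(n_loci=200, seed=11)
    return simulate_transcriptome(cfg)


@pytest.fixture(scope="session")
def small_truth():
    cfg = SimulationConfig(n_loci=40, seed=5)
    return simulate_transcriptome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
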