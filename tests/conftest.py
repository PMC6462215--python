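import numpy as np
import pytest

from nexuskit.config import PipelineConfig, SimConfig


@pytest.fixture
def pipe() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def small_sim() -> SimConfig:
    """A fast desk-scale experiment: 50 kb genome, 20 sites."""
    return SimConfig(genome_length=50_000, n_sites=20,
                     reads_per_bound_site=60, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
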