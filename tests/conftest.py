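import numpy as np
import pytest
from hypothesis import settings

from oxogprofiler import GenomeModel, SimulationConfig, make_genome

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_genome() -> GenomeModel:
    """Four 200-kb chromosomes (20 bins each at 10 kb) plus a mitochondrial contig."""
    return make_genome(4, 200_000, include_mito=True)


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Noise-free configuration: every read is a clean primary MAPQ-60 alignment."""
    return SimulationConfig(
        n_reads_per_sample=5_000,
        mapq_low_fraction=0.0,
        mito_fraction=0.0,
        duplicate_fraction=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
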