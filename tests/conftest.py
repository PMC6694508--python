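import numpy as np
import pytest

from polymir.config import SimulationConfig
from polymir.pipeline import run_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study: 2 chromosomes x 50 kb per subgenome, 20 loci."""
    return SimulationConfig(
        seed=5,
        n_chrom_per_subgenome=2,
        chrom_length=50_000,
        n_mirna_loci=20,
        mean_depth=20_000,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Full pipeline run on the small study; shared across tests."""
    return run_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
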