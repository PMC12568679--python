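import numpy as np
import pytest

from enhancerscape.synthetic_data import SimConfig, simulate_landscape


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale simulation: one 1.2-Mb chromosome, 80 sites, 60 genes."""
    return SimConfig(
        seed=11,
        n_chroms=1,
        chrom_length=1_200_000,
        n_genes=60,
        n_sites=80,
        min_site_spacing=2_000,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_landscape(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
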