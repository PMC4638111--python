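import numpy as np
import pytest

from hicstitch import (
    bin_genome,
    simulate_contacts,
    simulate_structure,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_chrom_bins():
    """Two chromosomes, two bins each, resolution 10."""
    return bin_genome({"chr1": 20, "chr2": 20}, 10)


@pytest.fixture(scope="session")
def small_genome():
    """Three short chromosomes in well-separated territories."""
    return simulate_structure(
        3, [20, 16, 12], territory_spacing=25.0, chain_step=1.0, seed=1
    )


@pytest.fixture(scope="session")
def small_noisefree_map(small_genome):
    return simulate_contacts(
        small_genome, alpha_true=1.0, count_scale=1.0, noise="none"
    )
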