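import numpy as np
import pytest

from crisprterm import ArraySpec, SimulationConfig, make_crispr_genome


@pytest.fixture(scope="session")
def small_config():
    """Two small arrays, two planted sites per spacer, compact genome."""
    return SimulationConfig(
        seed=11,
        genome_length=30_000,
        arrays=[ArraySpec("CRISPR-I", 6), ArraySpec("CRISPR-II", 6)],
        offtargets_per_spacer=2,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_crispr_genome(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
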