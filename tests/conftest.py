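import numpy as np
import pytest

from digenic_mapper.breeding_sim import StudyConfig
from digenic_mapper.genome import default_genome


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def sparse_genome():
    """Ten chromosomes with a minimal marker grid — fast simulations where
    only the causal loci matter."""
    return default_genome(markers_per_chromosome=2)


@pytest.fixture(scope="session")
def dense_genome():
    """The default study genome: 100 markers per chromosome."""
    return default_genome()


@pytest.fixture
def small_study_config():
    """Scaled-down breeding design for quick end-to-end runs."""
    return StudyConfig(
        n_f1_forward=20,
        n_f1_reverse=20,
        n_bc1_wild=40,
        n_bc1_mutant=60,
        n_f2=400,
        n_f23_families=12,
        f23_family_size=60,
        n_f23_selfed_per_family=4,
        f34_family_size=60,
    )
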