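import numpy as np
import pytest

from tifykit import motifs
from tifykit.simulate import FamilySimConfig, simulate_three_genome_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def models():
    return motifs.default_motif_models()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down scenario for fast module tests (6 focal genes, two
    duplications, one stress with one induced gene)."""
    return FamilySimConfig(
        n_per_subfamily={"JAZ": 3, "ZML": 2, "TIFY": 1},
        duplication_pairs={"JAZ": 1, "ZML": 1},
        n_up={"dehydration": 2, "cold": 3},
        n_down=1,
        n_supported=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return simulate_three_genome_scenario(small_config)
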