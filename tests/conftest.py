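import numpy as np
import pytest

from csdrmfa.genome import ChromosomeMap, ECOLI_K12
from csdrmfa.simulate import scenario_presets


@pytest.fixture(scope="session")
def ecoli():
    return ECOLI_K12


@pytest.fixture(scope="session")
def toy_chrom():
    """A small circular chromosome for hand-checkable fixtures."""
    return ChromosomeMap(
        name="toy", length=1_000_000, oriC_position=800_000,
        dif_position=300_000, ter_region=(200_000, 400_000),
    )


@pytest.fixture(scope="session")
def presets():
    return scenario_presets()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
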