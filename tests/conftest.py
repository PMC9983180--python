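import numpy as np
import pytest

from camoquant.observers import builtin_observer
from camoquant.spectra import WavelengthGrid, standard_illuminant_d65
from camoquant.synth import SimConfig


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def d65(grid):
    return standard_illuminant_d65(grid)


@pytest.fixture(scope="session")
def triplefin():
    return builtin_observer("triplefin")


@pytest.fixture(scope="session")
def goby():
    return builtin_observer("goby")


@pytest.fixture(scope="session")
def scorpionfish():
    return builtin_observer("scorpionfish")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_cfg():
    """A miniature study: small n, everything else at the default conditions."""
    return SimConfig(
        seed=7,
        n_fish={"S_maderensis": 3, "S_porcus": 2},
        n_fish_fluor={"S_maderensis": 2, "S_porcus": 2},
        n_fish_kinetics={"S_maderensis": 2, "S_porcus": 2},
    )
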