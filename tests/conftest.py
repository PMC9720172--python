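import numpy as np
import pytest

from oligotiler.thermo import ThermoConditions, default_nn_params


@pytest.fixture(scope="session")
def params():
    return default_nn_params()

@pytest.fixture(scope="session")
def cond():
    return ThermoConditions()


def random_acgt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
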