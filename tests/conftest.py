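import numpy as np
import pytest

from shapefold.energy import ThermoConstants, load_params


@pytest.fixture(scope="session")
def params():
    return load_params("default")


@pytest.fixture(scope="session")
def consts():
    return ThermoConstants()


def random_sequence(rng: np.random.Generator, n: int, gc_bias: float = 0.5) -> str:
    p = np.array([1 - gc_bias, gc_bias, gc_bias, 1 - gc_bias])
    p = p / p.sum()
    return "".join(rng.choice(list("AGCU"), size=n, p=p))
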