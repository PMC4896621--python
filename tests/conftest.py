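import numpy as np
import pytest

from nucmux import default_constraints, load_step_params


@pytest.fixture(scope="session")
def params():
    return load_step_params()


@pytest.fixture(scope="session")
def nuc_constraints():
    return default_constraints()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(n, seed=0):
    r = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in r.integers(0, 4, n))
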