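import numpy as np
import pytest

from mindgrad import build_spin_ensemble, generate_parcellation


@pytest.fixture(scope="session")
def parc16():
    return generate_parcellation(8, seed=1)


@pytest.fixture(scope="session")
def parc68():
    return generate_parcellation(34, seed=1)


@pytest.fixture(scope="session")
def parc308():
    return generate_parcellation(154, seed=11)


@pytest.fixture(scope="session")
def left68(parc68):
    return parc68.left_only()


@pytest.fixture(scope="session")
def ensemble68(parc68):
    return build_spin_ensemble(parc68, n_spins=500, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)
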