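import numpy as np
import pytest

from prrtdose import LU177
from prrtdose.study import load_study_dose_coefficients, load_study_tiacs, load_toy_s_matrix


@pytest.fixture(scope="session")
def lu177():
    return LU177


@pytest.fixture(scope="session")
def study_tiacs():
    return load_study_tiacs()


@pytest.fixture(scope="session")
def study_coeffs():
    return load_study_dose_coefficients()


@pytest.fixture(scope="session")
def toy_s():
    return load_toy_s_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231006)
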