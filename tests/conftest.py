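import numpy as np
import pytest

from cardiokit import build_model, make_toy_cell


@pytest.fixture(scope="session")
def toy():
    return make_toy_cell()


@pytest.fixture(scope="session")
def atrial():
    return build_model("atrial_MGTG")


@pytest.fixture(scope="session")
def ventricular():
    return build_model("ventricular_TNNP_epi")


@pytest.fixture(scope="session")
def purkinje():
    return build_model("purkinje_SANNBZ")


@pytest.fixture(scope="session")
def vgrid():
    return np.arange(-120.0, -29.9, 5.0)
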