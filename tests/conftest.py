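import numpy as np
import pytest

from lnocc import build_reference, generate_fixture
from lnocc.scf import DFTensors


@pytest.fixture(scope="session")
def water_ref():
    return build_reference(generate_fixture("water"), "svdz")


@pytest.fixture(scope="session")
def water_df(water_ref):
    return DFTensors(water_ref.basis, water_ref.aux)


@pytest.fixture(scope="session")
def methyl_ref():
    return build_reference(generate_fixture("methyl"), "svdz")


@pytest.fixture(scope="session")
def methyl_df(methyl_ref):
    return DFTensors(methyl_ref.basis, methyl_ref.aux)


@pytest.fixture(scope="session")
def ethyl_ref():
    return build_reference(generate_fixture("ethyl"), "sto-3g")


@pytest.fixture(scope="session")
def ethyl_df(ethyl_ref):
    return DFTensors(ethyl_ref.basis, ethyl_ref.aux)


@pytest.fixture(scope="session")
def hexane_ref():
    return build_reference(generate_fixture("closed_chain", 6), "sto-3g")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
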