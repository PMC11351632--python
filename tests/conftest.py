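import pytest

from oviductsim.flow_mechanics import FlowField
from oviductsim.tube_geometry import build_tube


@pytest.fixture(scope="session")
def tube20():
    return build_tube("20s")


@pytest.fixture(scope="session")
def tube20_endo():
    return build_tube("20s", with_endometriosis=True, lesion_count=5)


@pytest.fixture(scope="session")
def tube40():
    return build_tube("40s")


@pytest.fixture(scope="session")
def flow20(tube20):
    return FlowField(tube20)


@pytest.fixture(scope="session")
def flow20_endo(tube20_endo):
    return FlowField(tube20_endo)
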