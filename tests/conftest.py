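import pytest
from hypothesis import settings

from ventplume import ctd, thermo

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def seawater():
    return thermo.SeawaterBackground()


@pytest.fixture(scope="session")
def irinovskoe():
    return thermo.IRINOVSKOE


@pytest.fixture(scope="session")
def reference_bottles():
    return ctd.load_reference_bottles()
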