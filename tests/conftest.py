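import pytest
from hypothesis import settings

from sdmprimer import CodingSequence, default_catalog

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")
from sdmprimer.fixtures import akt1_pore_fixture


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def ndei_catalog(catalog):
    return catalog.select({"NdeI"})


@pytest.fixture(scope="session")
def akt1() -> CodingSequence:
    return akt1_pore_fixture()
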