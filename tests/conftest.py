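import pytest

from apollon.doped_pool import DopingModel
from apollon.structmodel import apollon_reference, apollon_structure


@pytest.fixture(scope="session")
def reference() -> str:
    return apollon_reference()


@pytest.fixture(scope="session")
def structure():
    return apollon_structure()


@pytest.fixture(scope="session")
def doping_model(reference) -> DopingModel:
    return DopingModel(reference, rate=0.21)
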