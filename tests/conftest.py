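import pytest

from cbtcea import StructuralConfig, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def cfg():
    return StructuralConfig()
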