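import pytest

from clipcea import EconParams, build_inputs


@pytest.fixture(scope="session")
def econ():
    return EconParams()


@pytest.fixture(scope="session")
def mitra_inputs():
    return build_inputs("mitra_fr")


@pytest.fixture(scope="session")
def coapt_inputs():
    return build_inputs("coapt")
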