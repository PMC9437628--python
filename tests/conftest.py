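import pytest

from sphingosim import build_flagship_model, build_toy_model


@pytest.fixture(scope="session")
def flagship():
    return build_flagship_model()


@pytest.fixture()
def toy():
    return build_toy_model()
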