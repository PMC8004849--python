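import pytest

from eutectics import UNIFAC, builtin_fixtures


@pytest.fixture(scope="session")
def registry():
    return builtin_fixtures()


@pytest.fixture(scope="session")
def unifac():
    return UNIFAC.default()
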