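import pytest

from cdexposure import default_parameters


@pytest.fixture(scope="session")
def params():
    """Default parameter catalogue, shared (gain memos accumulate across tests)."""
    return default_parameters()


@pytest.fixture()
def fresh_params():
    """An independent catalogue for tests that mutate scales or coefficients."""
    return default_parameters()
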