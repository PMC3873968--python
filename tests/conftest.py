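import pytest

from gccea import default_params


@pytest.fixture(scope="session")
def base_params():
    """Session-wide default parameter set; treat as read-only."""
    return default_params()


@pytest.fixture()
def params(base_params):
    """Fresh mutable copy of the defaults for each test."""
    return base_params.copy()
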