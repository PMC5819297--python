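import pytest

from chromoscan import ScoringScheme, generate_library


@pytest.fixture(scope="session")
def lib():
    """Default synthetic consensus library (seed 1)."""
    return generate_library(1)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()
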