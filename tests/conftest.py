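import pytest

from betle.constructs import build_synthetic_reporter


@pytest.fixture(scope="session")
def reporter():
    """The deterministic synthetic traffic-light reporter bundle."""
    return build_synthetic_reporter(7)
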