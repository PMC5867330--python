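import pytest

from p3c_oct import ScoringPolicy, default_instrument


@pytest.fixture(scope="session")
def instrument():
    return default_instrument()


@pytest.fixture
def policy():
    return ScoringPolicy()
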