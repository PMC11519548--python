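import pytest

from airmob import BottleState, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def bottle():
    """Standard incubation bottle at 1 atm for conversion checks."""
    return BottleState(
        headspace_volume=0.2, liquid_volume=0.05, pressure=1.013, temperature=293.15
    )
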