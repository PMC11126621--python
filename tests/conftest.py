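import pytest

from capnoduct import (AcousticMedium, deb_mixture, effective_medium,
                       initial_geometry, optimized_geometry)


@pytest.fixture(scope="session")
def air():
    return AcousticMedium(sound_speed=343.0, density=1.2047)


@pytest.fixture(scope="session")
def deb():
    """Effective medium of baseline dry exhaled breath (5% CO2)."""
    return effective_medium(deb_mixture(0))


@pytest.fixture(scope="session")
def geom_initial():
    return initial_geometry()


@pytest.fixture(scope="session")
def geom_optimized():
    return optimized_geometry()
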