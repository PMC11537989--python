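import numpy as np
import pytest

from flyhue import circuit as circ
from flyhue.stimgen import LEDSystem, sample_gamut, session_observation_counts


@pytest.fixture(scope="session")
def led_system():
    return LEDSystem()


@pytest.fixture(scope="session")
def gamut_small():
    """Small plain gamut set (no LED realization), for cheap tests."""
    return sample_gamut(60, seed=0)


@pytest.fixture(scope="session")
def gamut_realized(led_system):
    """LED-realized gamut set with Rh1 captures and session-style counts."""
    st = sample_gamut(150, seed=3, led_system=led_system)
    return st


@pytest.fixture(scope="session")
def example_template():
    return circ.example_template()


@pytest.fixture(scope="session")
def example_spec():
    return circ.example_spec()


@pytest.fixture(scope="session")
def observation_counts(gamut_realized):
    return session_observation_counts(gamut_realized, seed=4).astype(float)
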