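import numpy as np
import pytest

from tcrface import synthetic as syn


@pytest.fixture(scope="session")
def fixture_complex():
    """Idealized complex at the printed docking geometry (28 deg, 5 deg)."""
    return syn.make_complex(
        syn.FixtureParams(crossing_deg=28.0, incident_deg=5.0, shift_A=-3.0))


@pytest.fixture(scope="session")
def flat_complex():
    """Degenerate-free complex with zero crossing/incident/shift."""
    return syn.make_complex(
        syn.FixtureParams(crossing_deg=0.0, incident_deg=0.0, shift_A=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
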