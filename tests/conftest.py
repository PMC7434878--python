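import numpy as np
import pytest

from spinxes.spectral import default_fixture


@pytest.fixture(scope="session")
def fixture():
    """Calibrated default spectral fixture (cached for the whole run)."""
    return default_fixture()


@pytest.fixture(scope="session")
def kbeta_state_spectra(fixture):
    """Noiseless LS/intermediate/HS K-beta spectra on the default grid."""
    return fixture.state_spectra("Kbeta")
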