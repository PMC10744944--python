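import numpy as np
import pytest

from raftquant import EmissionSpectrum, LipidComposition


@pytest.fixture
def flat_spectrum():
    """Constant-intensity spectrum (100 a.u.) over 390-600 nm."""
    wl = np.arange(390.0, 601.0, 1.0)
    return EmissionSpectrum(wavelength_nm=wl,
                            intensity_au=np.full(wl.size, 100.0),
                            temperature_C=37.0)


@pytest.fixture
def ramp_spectrum():
    """Linear-ramp spectrum I(lambda) = lambda over 390-600 nm."""
    wl = np.arange(390.0, 601.0, 1.0)
    return EmissionSpectrum(wavelength_nm=wl, intensity_au=wl.copy(),
                            temperature_C=37.0)


@pytest.fixture
def popc_composition():
    return LipidComposition(pc_species="POPC", pc_frac=1.0)
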