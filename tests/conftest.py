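import numpy as np
import pytest

from fretassay import SimulationSpec, simulate_titration
from fretassay.spectra import EmissionSpectrum


@pytest.fixture(scope="session")
def noiseless_titration():
    """Study-design titration with no noise and one replicate per condition."""
    spec = SimulationSpec(seed=123, noise_cv=0.0, n_samples=1, n_reads=1)
    plate, ledger = simulate_titration(spec)
    return spec, plate, ledger


@pytest.fixture(scope="session")
def noisy_titration():
    """Study-design titration: 2% CV noise, 3 samples x 3 reads, fixed seed."""
    spec = SimulationSpec(seed=1, noise_cv=0.02)
    plate, ledger = simulate_titration(spec)
    return spec, plate, ledger


def make_spectrum(intensities, wavelengths=None, well_id="A1", excitation_nm=470.0):
    intensities = np.asarray(intensities, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(500.0, 500.0 + len(intensities))
    return EmissionSpectrum(
        well_id=well_id,
        excitation_nm=excitation_nm,
        wavelengths=np.asarray(wavelengths, dtype=float),
        intensities=intensities,
    )
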