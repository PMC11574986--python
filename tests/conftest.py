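import numpy as np
import pytest

from chemocal.design import calibration_table, validation_fixture
from chemocal.simulate import default_grid, default_phantoms, pure_spectrum, simulate_dataset


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def phantoms():
    return default_phantoms()


@pytest.fixture(scope="session")
def pure_matrix(phantoms, grid):
    """(3, 201) matrix of pure-component absorptivities."""
    return np.stack([pure_spectrum(c, grid) for c in phantoms])


@pytest.fixture(scope="session")
def noiseless_cal():
    """Calibration spectra with no noise and saturation disabled."""
    return simulate_dataset(calibration_table(), noise_sd=0.0, saturation_limit=None, seed=0)


@pytest.fixture(scope="session")
def noiseless_val():
    return simulate_dataset(validation_fixture(), noise_sd=0.0, saturation_limit=None, seed=0)


@pytest.fixture(scope="session")
def noisy_cal():
    """Calibration spectra at the default study conditions."""
    return simulate_dataset(calibration_table(), noise_sd=0.002, saturation_limit=3.0, seed=11)


@pytest.fixture(scope="session")
def noisy_val():
    return simulate_dataset(validation_fixture(), noise_sd=0.002, saturation_limit=3.0, seed=12)
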