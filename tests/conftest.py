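import numpy as np
import pytest

from npderep import datasets
from npderep.spectra_io import make_spectrum


@pytest.fixture(scope="session")
def cosmomycin_d():
    return datasets.cosmomycin_d_spectrum()


@pytest.fixture(scope="session")
def cosmomycin_c():
    return datasets.cosmomycin_c_spectrum()


@pytest.fixture(scope="session")
def compound12():
    return datasets.compound12_spectrum()


@pytest.fixture
def rng():
    return np.random.default_rng(20231107)


def random_small_spectrum(rng, n_peaks, spectrum_id="s"):
    """Tiny random spectrum for brute-force oracle comparisons."""
    precursor = float(rng.uniform(200.0, 1000.0))
    mz = np.sort(rng.uniform(50.0, precursor - 20.0, size=n_peaks))
    intensity = rng.uniform(0.1, 1.0, size=n_peaks)
    return make_spectrum(spectrum_id, precursor, mz, intensity)
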