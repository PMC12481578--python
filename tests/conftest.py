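import numpy as np
import pytest

from sersquant.spectra import Spectrum, SpectrumState, default_grid


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def grid():
    return default_grid()


@pytest.fixture
def random_spectrum(rng, grid):
    return Spectrum(grid, rng.uniform(0, 5, size=grid.size), SpectrumState.RAW)


def make_uniform_spectrum(y, state=SpectrumState.RAW, start=100.0, step=2.0):
    """Small helper: wrap an intensity vector on a uniform grid."""
    y = np.asarray(y, float)
    w = start + step * np.arange(y.size)
    return Spectrum(w, y, state)
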