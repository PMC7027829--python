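import numpy as np
import pytest

from specvar import SpectralCube


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def flat_cube():
    """4x4 cube, 31 uniform bands, spectrally flat at 0.5 everywhere."""
    wl = np.linspace(400.0, 700.0, 31)
    refl = np.full((4, 4, 31), 0.5)
    return SpectralCube(reflectance=refl, wavelengths=wl)


@pytest.fixture
def random_cube(rng):
    """6x6 cube with 40 bands of positive random reflectance."""
    wl = np.linspace(400.0, 2400.0, 40)
    refl = rng.uniform(0.05, 0.9, size=(6, 6, 40))
    return SpectralCube(reflectance=refl, wavelengths=wl)
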