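import numpy as np
import pytest

from rwct import GridImage, SeedMap, packaged_ct_fixture


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free packaged CT phantom with its standard seed map."""
    return packaged_ct_fixture(noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Packaged CT phantom with Gaussian noise at 0.1 of the dynamic range."""
    return packaged_ct_fixture(noise_sigma=0.1)


@pytest.fixture
def step_image():
    """6x6 two-region step image: left half 0, right half 1."""
    px = np.zeros((6, 6))
    px[:, 3:] = 1.0
    return GridImage(px)


@pytest.fixture
def step_seeds():
    return SeedMap.from_points([(2, 0, 1), (2, 5, 2)])
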