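import numpy as np
import pytest

from acnm import PhantomSpec, generate_head_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """The standard study phantom: 96x128x128, noise 0.02, bias 0.1, eye on."""
    return generate_head_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_head_phantom(PhantomSpec(noise_sd=0.0, bias_amplitude=0.0))


@pytest.fixture(scope="session")
def small_phantom():
    """A reduced head for whole-pipeline tests."""
    return generate_head_phantom(PhantomSpec(shape=(64, 96, 96), eye=False, seed=3))


@pytest.fixture
def disk_region():
    def make(shape=(80, 80), center=None, radius=10):
        yy, xx = np.indices(shape)
        cy, cx = center or ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    return make
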