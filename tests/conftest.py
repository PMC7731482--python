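import numpy as np
import pytest

from shgfb import synthetic


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Constant-ratio, noise-free, zero-background phantom (f = 2 b exactly)."""
    params = synthetic.PhantomParams(
        constant_fb=2.0, noise_scale=0.0, background_offset=0.0
    )
    pair, truth = synthetic.generate_image_pair((64, 64), params, seed=11)
    return pair, truth


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient cohort with a planted protective interface effect."""
    truth = synthetic.CohortTruth(beta_interface=-0.8, beta_bulk=0.0, beta_sodx=0.0)
    return synthetic.generate_cohort(300, truth, seed=42), truth


@pytest.fixture
def half_empty_image():
    """64x64: left half solid foreground, right half zeros."""
    img = np.zeros((64, 64))
    img[:, :32] = 100.0
    return img


@pytest.fixture
def patch_image_factory():
    """64x64 solid foreground with a centered k-by-k zero patch."""

    def make(k: int) -> np.ndarray:
        img = np.full((64, 64), 100.0)
        img[20 : 20 + k, 20 : 20 + k] = 0.0
        return img

    return make
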