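import numpy as np
import pytest
from hypothesis import settings

from limbtherm import PhantomParams, generate_recording
from limbtherm.phantom import phantom_rois, render_scene

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_params() -> PhantomParams:
    """A reduced-resolution phantom, noise-free by default."""
    return PhantomParams(image_shape=(96, 128), noise_sd_c=0.0)


@pytest.fixture
def noisy_params() -> PhantomParams:
    """Reduced-resolution phantom with sensor noise at the NETD scale."""
    return PhantomParams(image_shape=(96, 128), noise_sd_c=0.04)


@pytest.fixture
def small_scene(small_params):
    return render_scene(small_params)


@pytest.fixture
def small_rois(small_params):
    return phantom_rois(small_params)


@pytest.fixture
def clean_recording(noisy_params):
    """A 10-frame noisy recording with no corrupted frames."""
    return generate_recording(noisy_params, duration_s=1.0, rate_hz=10, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
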