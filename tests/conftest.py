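import numpy as np
import pytest
from hypothesis import settings

from stimkit import DisplayProfile, load_tutorial_test

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def display() -> DisplayProfile:
    """Small canonical display: 57.2957795 cm viewing distance makes
    1 degree of visual angle subtend ~1 cm."""
    return DisplayProfile(
        width_px=800,
        height_px=600,
        pixels_per_cm=10.0,
        refresh_rate=60.0,
        max_luminance=500.0,
        viewing_distance=57.2957795,
        model_name="test-panel",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tutorial():
    return load_tutorial_test()
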