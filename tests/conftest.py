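import numpy as np
import pytest

from periseg.phantom import PhantomConfig, generate_phantom
from periseg.types import CTSlice


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def lesion_phantom():
    """Default 128 px lesion phantom at 0.5 mm spacing (seed 7)."""
    return generate_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def control_phantom():
    return generate_phantom(PhantomConfig(group="control", seed=7))


@pytest.fixture(scope="session")
def small_lesion_phantom():
    """64 px lesion phantom at 1 mm spacing — cheap for heavier tests."""
    return generate_phantom(
        PhantomConfig(image_size=64, pixel_spacing_mm=1.0, seed=7)
    )


@pytest.fixture
def ramp_slice():
    h = np.arange(64, dtype=float).reshape(8, 8) * 10 - 300
    return CTSlice(h, (1.0, 1.0))
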