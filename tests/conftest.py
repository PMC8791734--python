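import numpy as np
import pytest

from osteoseg.phantom import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom family: 64x64 at 1 mm/px."""
    return PhantomSpec(image_height=64, image_width=64, pixel_spacing=1.0)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec, 12, seed=77)


def circle_mask(radius_mm: float, spacing: float = 0.5, size: int = 128) -> np.ndarray:
    """Rasterized disk centered in a size x size grid, pixel centers at
    (i + 0.5) * spacing."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = size * spacing / 2.0
    return (
        ((xx + 0.5) * spacing - c) ** 2 + ((yy + 0.5) * spacing - c) ** 2
        <= radius_mm**2
    ).astype(np.uint8)


@pytest.fixture(scope="session")
def circle_mask_factory():
    return circle_mask
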