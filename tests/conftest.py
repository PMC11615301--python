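import numpy as np
import pytest

from mitomorph import BinaryMask, Image2D
from mitomorph.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def tubular_phantom():
    """Default tubular phantom, noiseless (shared, read-only)."""
    return generate_phantom(PhantomSpec.for_regime("tubular", seed=5,
                                                   gaussian_noise_sd=0.0))


@pytest.fixture(scope="session")
def spherical_phantom():
    return generate_phantom(PhantomSpec.for_regime("spherical", seed=5,
                                                   gaussian_noise_sd=0.0))


def rasterized_disk(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = radius + pad
    gy, gx = np.mgrid[:n, :n]
    return (gy - c) ** 2 + (gx - c) ** 2 <= radius ** 2


def as_mask(arr, pixel_size=1.0) -> BinaryMask:
    return BinaryMask(np.asarray(arr, dtype=bool), pixel_size=pixel_size,
                      provenance="external")


def as_image(arr, pixel_size=1.0, name="img") -> Image2D:
    return Image2D(np.asarray(arr, dtype=float), pixel_size=pixel_size, name=name)
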