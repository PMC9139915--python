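import numpy as np
import pytest

from petresponse.pet_io import SUVImage, VOIMask


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_image(values, spacing=(2.0, 2.0, 2.0)):
    return SUVImage(np.asarray(values, dtype=float), spacing)


def make_mask(values, spacing=(2.0, 2.0, 2.0)):
    return VOIMask(np.asarray(values, dtype=bool), spacing)


@pytest.fixture
def sphere_phantom():
    """An 8 mm-radius hot sphere (SUV 6) in a cold background on a 2 mm grid."""
    shape = (13, 13, 13)
    center = np.array([6.0, 6.0, 6.0])
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    dist = np.sqrt(((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)) * 2.0
    mask = dist <= 8.0
    values = np.where(mask, 6.0, 0.1)
    return make_image(values), make_mask(mask)


@pytest.fixture
def textured_phantom(rng):
    """A random multi-level 6x6x6 VOI in a constant background."""
    shape = (10, 10, 10)
    mask = np.zeros(shape, dtype=bool)
    mask[2:8, 2:8, 2:8] = True
    values = np.full(shape, 0.1)
    values[mask] = rng.uniform(2.0, 5.0, size=int(mask.sum()))
    return make_image(values), make_mask(mask)
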