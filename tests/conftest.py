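import numpy as np
import pytest

from biofilmquant.segment import Component, ComponentMask
from biofilmquant.stack_io import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def blob_volume(rng):
    """Noisy two-class volume: background ~N(10, 2), a spherical foreground
    blob ~N(200, 10), plus the ground-truth mask."""
    shape = (32, 32, 32)
    zz, yy, xx = np.ogrid[:32, :32, :32]
    truth = (zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 10**2
    vol = rng.normal(10, 2, shape)
    vol[truth] = rng.normal(200, 10, int(truth.sum()))
    return np.clip(vol, 0, None), truth


def make_mask(occ, component=Component.protein):
    return ComponentMask(component, occ, threshold_used=1.0, method="manual")


@pytest.fixture
def small_stack(rng):
    vox = rng.uniform(0, 100, size=(2, 8, 8, 8))
    return ImageStack(vox, (1.0, 0.5, 0.5), ["protein", "lipid"])
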