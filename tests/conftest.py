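import logging

import numpy as np
import pytest
from hypothesis import settings

import lungfield as lf
from lungfield.model import LungFieldModel

logging.getLogger("lungfield").setLevel(logging.ERROR)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_spec():
    return lf.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def phantom_slice(phantom_spec):
    """(image, truth) of the first stack slice (no cartilage ring)."""
    return lf.make_slice(phantom_spec, 0)


@pytest.fixture(scope="session")
def phantom_stack(phantom_spec):
    return lf.make_stack(phantom_spec)


@pytest.fixture(scope="session")
def clean_slice():
    """Noise-free phantom slice for exact-separability checks."""
    spec = lf.PhantomSpec(seed=1, noise_sigma=0.0)
    return lf.make_slice(spec, 0)


@pytest.fixture(scope="session")
def fitted(phantom_spec):
    """Full pipeline fit on the 3-slice phantom stack (shared, read-only)."""
    model = LungFieldModel.from_phantom(phantom_spec)
    return model, model.fit()


@pytest.fixture(scope="session")
def two_phase_image():
    """128x128 disk of -800 HU on 0 HU background with 1% (8 HU) noise."""
    from skimage.draw import disk

    rng = np.random.default_rng(3)
    img = np.zeros((128, 128))
    rr, cc = disk((64, 64), 40)
    img[rr, cc] = -800.0
    truth = np.zeros((128, 128), dtype=bool)
    truth[rr, cc] = True
    return img + rng.normal(0.0, 8.0, img.shape), truth
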