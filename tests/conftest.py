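import numpy as np
import pytest

from sitsense.geometry import CameraConventions
from sitsense.scene import BoundingBox


@pytest.fixture
def conv():
    return CameraConventions()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_int_box(rng, span=20):
    x, y = rng.integers(-span, span, size=2)
    w, h = rng.integers(1, span, size=2)
    return BoundingBox(float(x), float(y), float(w), float(h))
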