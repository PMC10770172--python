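import numpy as np
import pytest
from skimage import draw

from lesionfuse.synthetic import LesionSpec, generate_lesion


def disc_mask(radius, pad=10):
    size = 2 * radius + 2 * pad + 1
    m = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((radius + pad, radius + pad), radius)
    m[rr, cc] = True
    return m


def square_mask(side, pad=10):
    m = np.zeros((side + 2 * pad, side + 2 * pad), dtype=bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def ellipse_mask(a, b, rotation=0.0, pad=10):
    size = 2 * max(a, b) + 2 * pad + 1
    m = np.zeros((size, size), dtype=bool)
    rr, cc = draw.ellipse(size // 2, size // 2, a, b, rotation=np.deg2rad(rotation))
    m[rr, cc] = True
    return m


@pytest.fixture
def plain_lesion():
    """A hairless, veil-free benign lesion (mid-brown, smooth border)."""
    return generate_lesion(LesionSpec(seed=42, palette=((123, 80, 48),)))


@pytest.fixture
def hairy_lesion():
    return generate_lesion(
        LesionSpec(seed=43, hair_count=10, hair_thickness=2.0, n_tones=2,
                   border_wave_amplitude=1.5)
    )
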