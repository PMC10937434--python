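import numpy as np
import pytest

from oarqa.core import Contour, ImageVolume, StructureSet


def sphere_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    sp = np.asarray(spacing)
    xs = (np.arange(shape[0]) * sp[0] - center[0])[:, None, None]
    ys = (np.arange(shape[1]) * sp[1] - center[1])[None, :, None]
    zs = (np.arange(shape[2]) * sp[2] - center[2])[None, None, :]
    return xs ** 2 + ys ** 2 + zs ** 2 <= radius ** 2


def box_mask(shape, lo, hi):
    m = np.zeros(shape, dtype=bool)
    m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return m


@pytest.fixture
def unit_grid():
    """60^3 grid at 1 mm isotropic spacing."""
    return dict(shape=(60, 60, 60), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def sphere_contour(unit_grid):
    mask = sphere_mask(unit_grid["shape"], (30, 30, 30), 10.0)
    return Contour(mask=mask, oar_type="sphere", spacing=unit_grid["spacing"])


def make_set(contours, image=None, set_id="s0"):
    s = StructureSet(image=image, set_id=set_id)
    for c in contours:
        s.add(c)
    return s
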