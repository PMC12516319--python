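import numpy as np
import pytest

from gastrukit import OrganoidMask, medial_axis
from gastrukit.synthetic import make_organoid_mask


@pytest.fixture(scope="session")
def straight_capsule():
    """Capsule with a 200 µm straight centerline and 50 µm caps at 1 µm/px."""
    mask, truth = make_organoid_mask(200.0, 50.0, 0.0, 1.0, seed=1)
    return mask, truth


@pytest.fixture(scope="session")
def straight_capsule_axis(straight_capsule):
    mask, _ = straight_capsule
    return medial_axis(mask)


@pytest.fixture(scope="session")
def disk_mask():
    """Near-perfect disk of radius 100 px (degenerate-skeleton regime)."""
    yy, xx = np.mgrid[0:220, 0:220]
    pixels = (xx - 110.0) ** 2 + (yy - 110.0) ** 2 <= 100.0**2
    return OrganoidMask(pixels, 1.0)


@pytest.fixture(scope="session")
def rectangle_mask():
    """200 x 50 px rectangle at 1 µm/px, with its exact body axis endpoints."""
    pixels = np.zeros((60, 214), dtype=bool)
    pixels[5:55, 7:207] = True
    return OrganoidMask(pixels, 1.0)
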