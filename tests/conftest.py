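import numpy as np
import pytest

from radiopathomics.synthetic import BACKGROUND_RGB, NUCLEUS_RGB


@pytest.fixture
def rng():
    return np.random.default_rng(20240113)


def paint(mask: np.ndarray) -> np.ndarray:
    """Render a boolean nucleus mask in the synthetic palette (no noise)."""
    img = np.empty(mask.shape + (3,), dtype=float)
    img[...] = BACKGROUND_RGB
    img[mask] = NUCLEUS_RGB
    return img.astype(np.uint8)


def disk_mask(shape, center, radius):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture
def two_disk_tile():
    """Two r=20 disks at centre distance 1.9r (overlap 10% of radius).

    Geometry of the split rule: the union's distance transform peaks at r
    inside each disk; the neck half-width at the circle intersection is
    sqrt(r^2 - (0.95 r)^2) = 0.312 r < 0.4 r, so the sure-foreground at
    fg_frac = 0.4 separates into two markers and watershed must yield two
    labels.  (At 20% overlap the neck is 0.436 r > 0.4 r and the rule
    provably cannot split - see the companion no-split test.)
    """
    r = 20
    m = disk_mask((128, 128), (64, 45), r) | disk_mask((128, 128), (64, 45 + int(1.9 * r)), r)
    return paint(m)
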