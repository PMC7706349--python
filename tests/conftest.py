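"""Shared fixtures: hand geometries and small synthetic studies."""

import numpy as np
import pytest

from rootscape.imaging import BinaryMask, Skeleton, skeletonize_mask


@pytest.fixture(scope="session")
def bar_mask() -> BinaryMask:
    """A 300 x 3 px vertical bar at 100 px/cm (3.00 cm deep, 0.03 cm wide)."""
    m = np.zeros((320, 40), dtype=bool)
    m[10:310, 18:21] = True
    return BinaryMask(mask=m, px_per_cm=100.0)


@pytest.fixture(scope="session")
def bar_skeleton(bar_mask) -> Skeleton:
    return skeletonize_mask(bar_mask)


@pytest.fixture(scope="session")
def t_root_mask() -> BinaryMask:
    """Vertical 300 px primary + one horizontal 100 px lateral at depth 50."""
    m = np.zeros((320, 160), dtype=bool)
    m[10:310, 20:23] = True  # primary
    m[59:62, 20:120] = True  # lateral
    return BinaryMask(mask=m, px_per_cm=100.0)


@pytest.fixture(scope="session")
def blob_masks() -> list[BinaryMask]:
    """Random connected blobs for property checks (seeded)."""
    rng = np.random.default_rng(42)
    masks = []
    for _ in range(5):
        m = np.zeros((80, 80), dtype=bool)
        r, c = 40, 40
        for _ in range(400):
            m[max(r - 2, 0) : r + 3, max(c - 2, 0) : c + 3] = True
            r = int(np.clip(r + rng.integers(-3, 4), 3, 76))
            c = int(np.clip(c + rng.integers(-3, 4), 3, 76))
        masks.append(BinaryMask(mask=m, px_per_cm=50.0))
    return masks
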