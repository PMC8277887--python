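import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


def make_disc(radius: int, pixel_size: float = 1.0):
    from cellscale import BinaryMask

    n = 2 * radius + 11
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    return BinaryMask((xx - c) ** 2 + (yy - c) ** 2 <= radius**2, pixel_size)


@pytest.fixture
def rect_mask():
    """Solid 20 x 10 px rectangle inside a larger frame."""
    from cellscale import BinaryMask

    grid = np.zeros((30, 40), dtype=bool)
    grid[10:20, 10:30] = True
    return BinaryMask(grid, 1.0)
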