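import numpy as np
import pytest

from grouptract.core import BinaryMask, ImageGrid, Streamline, Tractogram
from grouptract.synth import default_grid, make_label_volume


@pytest.fixture
def grid() -> ImageGrid:
    return default_grid((20, 20, 20))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def label_volume(grid):
    """Two disjoint boxes A (3^3 voxels) and B (2^3 voxels)."""
    return make_label_volume(
        {
            "A": {"shape": "box", "lo": (2, 2, 2), "hi": (4, 4, 4)},
            "B": {"shape": "box", "lo": (10, 10, 10), "hi": (11, 11, 11)},
        },
        grid,
    )


def random_tractogram(grid, rng, n_streamlines=3, n_points=5, lo=2.0, hi=17.0,
                      scalars=()):
    streamlines = []
    for _ in range(n_streamlines):
        pts = rng.uniform(lo, hi, size=(n_points, 3))
        sc = {name: rng.uniform(0, 1, size=n_points) for name in scalars}
        streamlines.append(Streamline(points=pts, scalars=sc))
    return Tractogram(streamlines=streamlines, grid=grid, space_tag="native")


def random_mask(grid, rng, density=0.2) -> BinaryMask:
    return BinaryMask(values=rng.random(grid.dims) < density, grid=grid)
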