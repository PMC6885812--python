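import numpy as np
import pytest

from neurocult.imaging_io import RoiMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_grid_rois(n_rows=10, n_cols=5, block=16, pitch=20):
    """Disjoint square ROIs laid out on a grid, labels 1..n in raster order."""
    img = np.zeros((n_rows * pitch, n_cols * pitch), dtype=np.int32)
    label = 1
    for r in range(n_rows):
        for c in range(n_cols):
            img[
                r * pitch + 2 : r * pitch + 2 + block,
                c * pitch + 2 : c * pitch + 2 + block,
            ] = label
            label += 1
    return RoiMap(img)


@pytest.fixture
def grid_rois():
    return make_grid_rois()
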