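import numpy as np
import pytest

from landgen import LandscapeRaster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_raster(
    seed: int,
    max_size: int = 12,
    max_classes: int = 4,
    nodata_frac: float = 0.15,
) -> LandscapeRaster:
    """Small random categorical raster, optionally with NODATA holes."""
    r = np.random.default_rng(seed)
    rows = int(r.integers(1, max_size + 1))
    cols = int(r.integers(1, max_size + 1))
    n_classes = int(r.integers(1, max_classes + 1))
    codes = r.integers(1, n_classes + 1, size=(rows, cols)).astype(np.int32)
    if r.random() < 0.5:
        holes = r.random((rows, cols)) < nodata_frac * r.random()
        codes[holes] = -1
    if codes.max() < 0:  # keep at least one valid cell
        codes[0, 0] = 1
    return LandscapeRaster(codes)
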