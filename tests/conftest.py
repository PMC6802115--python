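import numpy as np
import pytest

from ffosheet import Box, SheetModelParams


@pytest.fixture
def params():
    return SheetModelParams()


@pytest.fixture
def slab_box():
    """The standard observation region: 2 x 2 µm membrane patch, 300 nm deep."""
    return Box.from_extent((2000.0, 2000.0, 300.0))


def brute_force_profile(coords: np.ndarray) -> np.ndarray:
    """Independent O(n²) oracle: directed shell counts over all ordered pairs."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        return np.zeros(8, dtype=np.int64)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    off = d[~np.eye(n, dtype=bool)]  # each ordered pair once
    idx = np.floor(off / 5.0).astype(int)
    sel = (idx >= 2) & (idx <= 9)
    return np.bincount(idx[sel] - 2, minlength=8).astype(np.int64)


@pytest.fixture
def brute_profile():
    return brute_force_profile
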