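import numpy as np
import pytest

import hornwalk as hw


@pytest.fixture
def rules():
    return hw.DEFAULT_RULES


@pytest.fixture
def open_landscape():
    """9x9 fully passable toy: central escape cell, everything within 400 m."""
    n = 9
    slope = np.zeros((n, n))
    slope[4, 4] = 45.0
    zeros = np.zeros((n, n), dtype=np.int64)
    return hw.make_toy_landscape(slope, np.zeros((n, n)), zeros, zeros)


@pytest.fixture
def corridor_landscape():
    """Sealed 3x7 corridor: single passable row of escape cells, water walls.

    From the left end the only legal move at every step is one cell to
    the right (walls and no-backtrack), so the trajectory is the unique
    path col 1 -> col 5, ending stuck.
    """
    slope = np.zeros((3, 7))
    slope[1, 1:6] = 45.0
    water = np.ones((3, 7), dtype=np.int64)
    water[1, 1:6] = 0
    zeros = np.zeros((3, 7), dtype=np.int64)
    return hw.make_toy_landscape(slope, np.zeros((3, 7)), water, zeros)


@pytest.fixture
def synthetic_landscape():
    return hw.make_synthetic_landscape(hw.SynthParams(n_rows=60, n_cols=60, rng_seed=3))


def brute_force_escape_distance(mask, cell_size, metric="euclidean"):
    """Independent oracle: min over all escape cells of the pairwise distance."""
    mask = np.asarray(mask, dtype=bool)
    n_rows, n_cols = mask.shape
    esc = np.argwhere(mask)
    out = np.full(mask.shape, np.inf)
    for r in range(n_rows):
        for c in range(n_cols):
            for er, ec in esc:
                if metric == "euclidean":
                    d = np.hypot(r - er, c - ec) * cell_size
                else:
                    d = max(abs(r - er), abs(c - ec)) * cell_size
                out[r, c] = min(out[r, c], d)
    return out
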