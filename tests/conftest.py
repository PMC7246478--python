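import numpy as np
import pytest
from hypothesis import settings

from noisecross.footprints import FootprintGrid, FootprintKey

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def make_grid():
    """Factory for small footprint grids with controllable geometry and values."""

    def _make(
        key=None,
        origin=(0.0, 1000.0),
        cell=250.0,
        shape=(5, 5),
        lae=None,
        lamax=None,
        fill=70.0,
    ):
        if key is None:
            key = FootprintKey(2010, "MEDIUM", "DEP_N", "departure")
        ny, nx = shape
        if lae is None:
            lae = np.full((ny, nx), fill)
        lae = np.asarray(lae, dtype=float)
        if lamax is None:
            lamax = lae - 8.0
        return FootprintGrid(key=key, origin=origin, cell_size=cell, lae=lae, lamax=np.asarray(lamax, dtype=float))

    return _make


@pytest.fixture
def random_grid(make_grid):
    """Factory for a seeded random grid of a given size."""

    def _make(rng, ny=6, nx=7, cell=250.0, key=None):
        lae = rng.uniform(20.0, 95.0, size=(ny, nx))
        return make_grid(key=key, shape=(ny, nx), cell=cell, lae=lae, lamax=lae - rng.uniform(2, 12))

    return _make
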