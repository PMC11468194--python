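import numpy as np
import pytest

from fmripipe.types import Grid, Volume4D


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture()
def small_grid():
    return Grid.isotropic((8, 8, 6), 3.0)


@pytest.fixture()
def random_vol(rng, small_grid):
    """A small random 4D volume with slice timing metadata."""
    data = 100.0 + rng.standard_normal((8, 8, 6, 24))
    st = np.linspace(0.0, 1.9, 6)
    return Volume4D(grid=small_grid, data=data, tr=2.0, slice_times=st)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """Session-cached noiseless single-echo phantom with known tissue truth."""
    from fmripipe.synth import make_phantom

    vol, truth = make_phantom(
        dims=(20, 20, 12), n_volumes=30, noise_tsnr=0.0, drift_percent=0.0, seed=11
    )
    return vol, truth
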