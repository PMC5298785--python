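import numpy as np
import pytest

from fieldpheno.canopy_traits import fit_ground_plane
from fieldpheno.synthetic_field import (
    default_rig,
    make_board,
    make_plot_scene,
    render_board_views,
)


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def board():
    return make_board()


@pytest.fixture(scope="session")
def noiseless_views(rig, board):
    """10 noiseless board views in all three cameras, plus true poses."""
    return render_board_views(board, rig, n_views=10, noise_sigma_px=0.0, seed=11)


@pytest.fixture(scope="session")
def plot_scene():
    """Default 10-plant plot at 76 cm row spacing with ground truth."""
    return make_plot_scene(seed=42)


@pytest.fixture(scope="session")
def plot_ground(plot_scene):
    cloud, _ = plot_scene
    return fit_ground_plane(cloud, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
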