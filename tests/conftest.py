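import pytest

from follicle_cnd import simulate
from follicle_cnd.geometry import FollicleGeometry
from follicle_cnd.imaging import FollicleScene


@pytest.fixture(scope="session")
def wt_traces():
    """Wild-type default simulation over the full 5-h window."""
    return simulate(t_end=300.0, dt_out=0.25)


@pytest.fixture(scope="session")
def small_geometry():
    return FollicleGeometry()


@pytest.fixture()
def small_scene(small_geometry):
    """Down-scaled scene (160x160, 2.5 um/px) for fast rendering tests."""
    return FollicleScene(geometry=small_geometry, shape=(160, 160),
                         pixel_size=2.5, seed=11)


@pytest.fixture(scope="session")
def short_wt_traces():
    """Wild-type simulation of the first hour (for imaging tests)."""
    return simulate(t_end=60.0, dt_out=0.5)
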