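import numpy as np
import pytest

from tractshape import synthetic


@pytest.fixture
def small_cylinder():
    """Dense thin cylinder: every touched density voxel has count >= 2."""
    return synthetic.make_cylinder(
        length_mm=40, diameter_mm=4, n_streamlines=400, seed=7, label="cyl"
    )


@pytest.fixture
def semicircle():
    return synthetic.make_arc(
        radius_mm=50, angle_rad=np.pi, tube_diameter_mm=4, n_streamlines=100, seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_polyline(rng, n_points=10, box=50.0):
    return rng.uniform(0, box, size=(n_points, 3))
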