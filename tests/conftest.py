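import numpy as np
import pytest
from hypothesis import settings

import fibermap as fm

settings.register_profile("fibermap", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("fibermap")


@pytest.fixture
def plus_plane():
    """5x5 plus sign: vertical and horizontal 5-pixel lines crossing at (2, 2)."""
    plane = np.zeros((5, 5), dtype=np.uint8)
    plane[2, :] = 1
    plane[:, 2] = 1
    return plane


@pytest.fixture
def x_plane():
    """5x5 X: two diagonal 5-pixel lines crossing at (2, 2)."""
    plane = np.zeros((5, 5), dtype=np.uint8)
    for i in range(5):
        plane[i, i] = 1
        plane[i, 4 - i] = 1
    return plane


@pytest.fixture
def horizontal_line_plane():
    """20x20 plane with a single 10-pixel horizontal line."""
    plane = np.zeros((20, 20), dtype=np.uint8)
    plane[10, 5:15] = 1
    return plane


def make_stack(planes, z_spacing=1.0, label="test"):
    planes = np.asarray(planes, dtype=np.uint8)
    geometry = fm.StackGeometry(n_sections=planes.shape[0], z_spacing=z_spacing)
    return fm.TraceStack(planes=planes, geometry=geometry, label=label)


@pytest.fixture
def line_stack():
    """3 planes, each with one disjoint 10-pixel horizontal line."""
    planes = np.zeros((3, 32, 32), dtype=np.uint8)
    for z in range(3):
        planes[z, 5 + 8 * z, 4:14] = 1
    return make_stack(planes)


def two_cluster_spec(seed=11, n_fibers=80, kappa=100.0, length_range=(15.0, 40.0)):
    """Two spatially separated clusters at 30 and 120 degrees."""
    return fm.SyntheticFieldSpec(
        height=512,
        width=512,
        n_sections=10,
        seed=seed,
        clusters=(
            fm.ClusterSpec(
                mean_axis_deg=30.0,
                kappa=kappa,
                n_fibers=n_fibers,
                region=(8, 8, 504, 248),
                length_range=length_range,
            ),
            fm.ClusterSpec(
                mean_axis_deg=120.0,
                kappa=kappa,
                n_fibers=n_fibers,
                region=(8, 264, 504, 504),
                length_range=length_range,
            ),
        ),
    )
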