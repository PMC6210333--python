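import numpy as np
import pytest

from leaf3d.cloud import PointCloud
from leaf3d.phantom import generate_leaf


@pytest.fixture
def tiny_cloud() -> PointCloud:
    """Three points with distinct colors and labels, for I/O round trips."""
    points = np.array([[0.0, 0.0, 0.0], [1.25, -2.5, 0.75], [3.0, 4.0, 5.0]])
    colors = np.array([[10, 200, 30], [120, 120, 120], [0, 255, 0]], dtype=np.uint8)
    labels = np.array([1, 0, 2])
    return PointCloud(points, colors, labels)


def single_leaf_cloud(a=3.0, inclination=30.0, noise=0.0, seed=0, azimuth=0.0,
                      density=250.0):
    """One circular-to-elliptic leaf phantom as a labeled PointCloud."""
    rng = np.random.default_rng(seed)
    cloud, truth = generate_leaf(
        a=a, b=a, inclination_deg=inclination, azimuth_deg=azimuth,
        points_per_cm2=density, noise_sigma=noise, rng=rng,
    )
    return cloud, truth
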