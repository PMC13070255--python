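import numpy as np
import pytest
from shapely.geometry import MultiPoint

from efferoquant.smlm import Cluster, ClusterSet


def cluster_from_points(points: np.ndarray) -> Cluster:
    """Build a Cluster directly from coordinates (bypassing OPTICS)."""
    points = np.asarray(points, dtype=float)
    hull = MultiPoint(points).convex_hull
    if hull.geom_type != "Polygon":
        hull = hull.buffer(1e-6)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    return Cluster(
        indices=np.arange(len(points)),
        points=points,
        centroid=points.mean(axis=0),
        boundary=hull,
        diameter_nm=float(d.max()),
    )


def cluster_set(*point_arrays) -> ClusterSet:
    return ClusterSet(
        clusters=[cluster_from_points(p) for p in point_arrays],
        noise_indices=np.empty(0, dtype=int),
        params={},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
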