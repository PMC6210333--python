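"""Per-leaf structural traits: voxel-count leaf area and plane-fit
inclination angle.

Leaf area: the leaf's points are re-voxelized on a grid whose Z voxel is
coarser than XY (default 3x), damping vertical surface noise that would
otherwise stack spurious voxels; the area is then the number of occupied
voxels times the horizontal face area s².

Inclination: a plane is fitted by total least squares to the points near
the leaf centroid (the central lamina, excluding curled edges), and the
angle between the plane and the horizontal is taken from the normal
vector, in [0°, 90°].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cloud import PointCloud
from .voxel import voxelize

__all__ = ["leaf_area", "leaf_inclination", "measure_leaves"]


def _leaf_points(cloud: PointCloud, leaf_number: int) -> np.ndarray:
    if cloud.labels is None:
        raise ValueError("point cloud has no leaf labels")
    pts = cloud.points[cloud.labels == leaf_number]
    if len(pts) == 0:
        raise ValueError(f"no points carry leaf number {leaf_number}")
    return pts


def leaf_area(
    cloud: PointCloud,
    leaf_number: int,
    voxel_size_xy: float = 0.1,
    z_rebin_factor: float = 3.0,
) -> float:
    """Leaf area (cm²) by voxel counting.

    The leaf's own points are re-voxelized at
    ``(s, s, z_rebin_factor * s)`` and the area is the occupied-voxel count
    times ``s**2`` — the horizontal face area.  Counting occupancy, not
    density, makes the estimate invariant to duplicated points.
    """
    if voxel_size_xy <= 0 or z_rebin_factor <= 0:
        raise ValueError("voxel_size_xy and z_rebin_factor must be positive")
    pts = _leaf_points(cloud, leaf_number)
    s = float(voxel_size_xy)
    sub = PointCloud(pts, np.zeros((len(pts), 3), dtype=np.uint8))
    grid = voxelize(sub, (s, s, z_rebin_factor * s))
    return float(grid.occupancy.sum()) * s * s


def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the total-least-squares plane through ``points``.

    The normal is the principal direction of smallest variance of the
    centered coordinates (last right-singular vector).  Raises on fewer
    than 3 points or a (near-)collinear configuration, where the plane is
    not defined.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError(f"plane fit needs >= 3 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= max(svals[0], 1.0) * 1e-12:
        raise ValueError("points are collinear; plane normal undefined")
    return vt[-1]


def leaf_inclination(
    cloud: PointCloud,
    leaf_number: int,
    plane_fit_radius_frac: float = 0.3,
) -> float:
    """Leaf inclination angle (degrees in [0, 90]) from a central plane fit.

    The fit neighborhood is the set of leaf points within
    ``plane_fit_radius_frac`` x (leaf bounding-box diagonal) of the leaf
    centroid; the inclination is ``arccos(|n . z|)`` for the fitted unit
    normal n — the angle between the leaf plane and the horizontal.  The
    estimate is invariant to rotation about the vertical axis and to
    uniform scaling.
    """
    if not 0.0 < plane_fit_radius_frac <= 1.0:
        raise ValueError(
            f"plane_fit_radius_frac must be in (0, 1], got {plane_fit_radius_frac}"
        )
    pts = _leaf_points(cloud, leaf_number)
    centroid = pts.mean(axis=0)
    diagonal = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    if diagonal == 0.0:
        raise ValueError(f"leaf {leaf_number} is degenerate (zero extent)")
    radius = plane_fit_radius_frac * diagonal
    near = pts[np.linalg.norm(pts - centroid, axis=1) <= radius]
    try:
        normal = fit_plane_normal(near)
    except ValueError as exc:
        raise ValueError(
            f"cannot fit a plane to leaf {leaf_number}: {exc}"
        ) from exc
    cos_tilt = np.clip(abs(normal[2]), 0.0, 1.0)
    return float(np.degrees(np.arccos(cos_tilt)))


def measure_leaves(
    cloud: PointCloud,
    voxel_size_xy: float = 0.1,
    z_rebin_factor: float = 3.0,
    plane_fit_radius_frac: float = 0.3,
) -> pd.DataFrame:
    """Traits table for every leaf present in the cloud's labels.

    Returns a DataFrame with one row per leaf number (ascending):
    ``leaf_number, voxel_count, area_cm2, inclination_deg,
    centroid_x, centroid_y, centroid_z``.
    """
    if cloud.labels is None:
        raise ValueError("point cloud has no leaf labels")
    rows = []
    s = float(voxel_size_xy)
    for leaf in np.unique(cloud.labels):
        if leaf == 0:
            continue
        pts = cloud.points[cloud.labels == leaf]
        area = leaf_area(cloud, int(leaf), s, z_rebin_factor)
        angle = leaf_inclination(cloud, int(leaf), plane_fit_radius_frac)
        centroid = pts.mean(axis=0)
        rows.append(
            {
                "leaf_number": int(leaf),
                "voxel_count": int(round(area / (s * s))),
                "area_cm2": area,
                "inclination_deg": angle,
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "centroid_z": centroid[2],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "leaf_number", "voxel_count", "area_cm2", "inclination_deg",
            "centroid_x", "centroid_y", "centroid_z",
        ],
    )
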