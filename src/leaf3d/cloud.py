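"""Colored point clouds and the green-index leaf filter.

A plant scan is held as a :class:`PointCloud`: XYZ coordinates in
centimetres (assumed already metrically scaled), per-point RGB colours in
0-255, and an optional per-point leaf label (0 = unassigned).  Non-leaf
material (branches, soil, reconstruction noise) is removed by thresholding
the normalized green value G/(R+G+B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointCloud", "filter_green", "green_index"]


@dataclass
class PointCloud:
    """A colored 3D point cloud with optional per-point leaf labels.

    Parameters
    ----------
    points : (n, 3) float array
        XYZ coordinates in cm.
    colors : (n, 3) uint8 array
        RGB in 0-255.
    labels : (n,) int array, optional
        Leaf number per point; 0 means unassigned/background.
    """

    points: np.ndarray
    colors: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.colors = np.asarray(self.colors).reshape(-1, 3)
        if len(self.points) != len(self.colors):
            raise ValueError(
                f"points ({len(self.points)}) and colors ({len(self.colors)}) "
                "must have the same length"
            )
        if not np.all(np.isfinite(self.points)):
            bad = int(np.flatnonzero(~np.isfinite(self.points).all(axis=1))[0])
            raise ValueError(f"non-finite coordinate at point index {bad}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
            if len(self.labels) != len(self.points):
                raise ValueError("labels must match number of points")
            if np.any(self.labels < 0):
                raise ValueError("labels must be non-negative (0 = unassigned)")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Return the sub-cloud at a boolean mask or index array."""
        return PointCloud(
            self.points[mask],
            self.colors[mask],
            None if self.labels is None else self.labels[mask],
        )

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(self.points, self.colors, labels)


def green_index(colors: np.ndarray) -> np.ndarray:
    """Normalized green value G/(R+G+B) per point.

    Black points (R=G=B=0) have an undefined index and are returned as -1
    so that any threshold in (0, 1) removes them.
    """
    c = np.asarray(colors, dtype=np.float64)
    total = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(total > 0, c[:, 1] / np.where(total > 0, total, 1.0), -1.0)
    return g


def filter_green(cloud: PointCloud, threshold: float = 0.4) -> PointCloud:
    """Remove non-green points: keep points with G/(R+G+B) >= ``threshold``.

    The cut is strict on the low side — a point whose index is exactly the
    threshold is retained.  Black (0,0,0) points have no defined index and
    are always removed.  An empty result is returned with a warning rather
    than raising, so a clutter-only scan degrades gracefully.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    keep = green_index(cloud.colors) >= threshold
    if not keep.any():
        warnings.warn("green filter removed every point", stacklevel=2)
    return cloud.select(keep)
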