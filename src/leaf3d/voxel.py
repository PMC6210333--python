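"""Voxelization of point clouds into occupancy/label grids.

Each point is mapped to the integer lattice by rounding its grid
coordinate to the nearest voxel index (round half away from zero); a voxel
containing at least one point gets occupancy 1.  The grid stores its world
origin and per-axis voxel size, so indices convert back to voxel-centre
world coordinates losslessly.  Anisotropic grids (Z coarser than XY) are
used for leaf-area estimation, where vertical surface noise would
otherwise inflate the voxel count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud

__all__ = ["VoxelGrid", "voxelize", "round_half_away", "save_grid", "load_grid"]


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going away from zero.

    numpy's ``round`` rounds half to even; voxelization here fixes the
    half-away convention instead so that indices are a pure function of the
    coordinate, independent of parity.
    """
    x = np.asarray(x)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


@dataclass
class VoxelGrid:
    """Occupancy + label lattice with a world anchoring.

    Attributes
    ----------
    origin : (3,) float
        World coordinates (cm) of the voxel-centre at index (0, 0, 0).
    voxel_size : (3,) float
        Edge length (cm) per axis; Z may differ from XY.
    occupancy : (nx, ny, nz) uint8
        1 where at least one point landed.
    labels : (nx, ny, nz) int32
        Leaf number per voxel, 0 = unassigned; nonzero only on occupied voxels.
    """

    origin: np.ndarray
    voxel_size: np.ndarray
    occupancy: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValueError(f"voxel_size must be strictly positive, got {self.voxel_size}")
        self.occupancy = np.asarray(self.occupancy, dtype=np.uint8)
        if self.occupancy.ndim != 3 or min(self.occupancy.shape) < 1:
            raise ValueError("occupancy must be a non-empty 3D array")
        if self.labels is None:
            self.labels = np.zeros(self.occupancy.shape, dtype=np.int32)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int32)
            if self.labels.shape != self.occupancy.shape:
                raise ValueError("labels shape must match occupancy shape")
            if np.any((self.labels != 0) & (self.occupancy == 0)):
                raise ValueError("labels may be nonzero only on occupied voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates to (possibly out-of-bounds) voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return round_half_away((pts - self.origin) / self.voxel_size)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centres at the given indices."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return idx * self.voxel_size + self.origin

    def point_labels(self, points: np.ndarray) -> np.ndarray:
        """Label of the voxel each point falls in (0 if outside the grid)."""
        idx = self.world_to_index(points)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.zeros(len(idx), dtype=np.int64)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def voxelize(cloud: PointCloud, voxel_size) -> VoxelGrid:
    """Convert a point cloud into a binary occupancy grid.

    The origin is placed at the minimum corner of the cloud so all indices
    are non-negative; duplicated points and point order do not affect the
    result.

    Parameters
    ----------
    cloud : PointCloud
        Non-empty cloud with finite coordinates.
    voxel_size : float or (sx, sy, sz)
        Voxel edge length in cm; a scalar gives a cubic voxel.
    """
    if len(cloud) == 0:
        raise ValueError("cannot voxelize an empty point cloud")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=np.float64), (3,)).copy()
    if np.any(vs <= 0):
        raise ValueError(f"voxel_size must be positive, got {vs}")
    origin = cloud.points.min(axis=0)
    idx = round_half_away((cloud.points - origin) / vs)
    shape = tuple(int(m) + 1 for m in idx.max(axis=0))
    occ = np.zeros(shape, dtype=np.uint8)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
    return VoxelGrid(origin=origin, voxel_size=vs, occupancy=occ)


def save_grid(path: str | os.PathLike, grid: VoxelGrid) -> None:
    """Save a grid to ``.npz`` (lossless round trip with :func:`load_grid`)."""
    np.savez_compressed(
        path,
        origin=grid.origin,
        voxel_size=grid.voxel_size,
        occupancy=grid.occupancy,
        labels=grid.labels,
    )


def load_grid(path: str | os.PathLike) -> VoxelGrid:
    with np.load(path) as data:
        return VoxelGrid(
            origin=data["origin"],
            voxel_size=data["voxel_size"],
            occupancy=data["occupancy"],
            labels=data["labels"],
        )
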