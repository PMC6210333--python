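"""End-to-end segmentation pipeline: green filter, voxelization, top-view
seeding, and 3D label growth back onto the points."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud, green_index
from .config import PipelineConfig
from .expand import (
    expand_attributes,
    merge_seeds_by_component,
    project_seeds,
    relabel_consecutive,
    simple_projection_segment,
)
from .topview import fill_holes, initial_segment, project_topview, shrink_seeds
from .voxel import VoxelGrid, voxelize

__all__ = ["SegmentationResult", "segment_plant"]


@dataclass
class SegmentationResult:
    """Everything the pipeline produced for one plant.

    ``labels`` is per-point over the ORIGINAL cloud (0 for points cut by
    the green filter or left unassigned); intermediate rasters are kept for
    inspection.
    """

    labels: np.ndarray
    grid: VoxelGrid
    topview_mask: np.ndarray
    initial_labels2d: np.ndarray
    seeds2d: np.ndarray
    n_leaves: int
    n_unreached_voxels: int
    method: str
    config: PipelineConfig = field(repr=False)

    def labeled_cloud(self, cloud: PointCloud) -> PointCloud:
        return cloud.with_labels(self.labels)


def segment_plant(
    cloud: PointCloud,
    config: PipelineConfig | None = None,
    method: str = "expand",
) -> SegmentationResult:
    """Segment a plant point cloud into individual leaves.

    Steps: cut non-green points; voxelize at ``voxel_size_xy``; project to
    the top view and fill sampling holes; watershed the distance transform
    into an initial 2D segmentation; contract each 2D leaf to a seed;
    project seeds onto the topmost occupied voxel per column and grow them
    three-dimensionally (``method="expand"``), or stamp the 2D labels down
    every column (``method="simple"``, the occlusion-blind baseline).
    Finally each input point inherits its voxel's label.

    Deterministic: identical cloud + config always yields identical labels.
    """
    if method not in ("expand", "simple"):
        raise ValueError(f"method must be 'expand' or 'simple', got {method}")
    config = config or PipelineConfig()

    keep = green_index(cloud.colors) >= config.green_threshold
    green = cloud.select(keep)
    if len(green) == 0:
        raise ValueError("no green points remain after filtering; cannot segment")
    grid = voxelize(green, config.voxel_size_xy)

    mask = fill_holes(project_topview(grid))
    initial2d = initial_segment(
        mask, h=config.h_maxima, connectivity=config.connectivity_2d,
        smooth_sigma=config.marker_smooth_sigma,
        mask_smooth_radius=config.mask_smooth_radius,
    )

    if method == "expand":
        seeds2d = shrink_seeds(initial2d, config.shrink_factor)
        seed_voxels = project_seeds(seeds2d, grid)
        if config.merge_seed_components:
            seed_voxels = merge_seeds_by_component(
                grid, seed_voxels, config.connectivity_3d
            )
        labeled_grid, n_unreached = expand_attributes(
            grid, seed_voxels, config.connectivity_3d
        )
        labeled_grid.labels = relabel_consecutive(labeled_grid.labels)
    else:
        seeds2d = initial2d
        labeled_grid = simple_projection_segment(initial2d, grid)
        occ = labeled_grid.occupancy.astype(bool)
        n_unreached = int(np.count_nonzero(occ & (labeled_grid.labels == 0)))

    point_labels = np.zeros(len(cloud), dtype=np.int64)
    point_labels[keep] = labeled_grid.point_labels(green.points)
    return SegmentationResult(
        labels=point_labels,
        grid=labeled_grid,
        topview_mask=mask,
        initial_labels2d=initial2d,
        seeds2d=seeds2d,
        n_leaves=int(labeled_grid.labels.max()),
        n_unreached_voxels=n_unreached,
        method=method,
        config=config,
    )
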