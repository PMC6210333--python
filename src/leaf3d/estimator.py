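"""scikit-learn style front end to the segmentation pipeline.

:class:`LeafSegmenter` behaves like a clustering estimator: ``fit`` takes
an ``(n, 6)`` array of ``x, y, z, r, g, b`` rows (or a
:class:`~leaf3d.cloud.PointCloud`) and exposes per-point leaf numbers in
``labels_`` (0 = background/non-green, leaves numbered 1..K), so it can be
cloned, grid-searched and composed like any other sklearn estimator.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .cloud import PointCloud
from .config import PipelineConfig
from .pipeline import segment_plant
from .traits import measure_leaves

__all__ = ["LeafSegmenter"]


class LeafSegmenter(ClusterMixin, BaseEstimator):
    """Segment a plant point cloud into individual leaves.

    Parameters mirror :class:`~leaf3d.config.PipelineConfig`; see there
    for meanings and units.

    Attributes
    ----------
    labels_ : (n,) int array
        Leaf number per input point; 0 marks points cut by the green
        filter or left unassigned.
    n_leaves_ : int
        Number of distinct leaves in the final labeling.
    grid_ : VoxelGrid
        The labeled voxel grid.
    result_ : SegmentationResult
        Full pipeline output (intermediate rasters included).

    Examples
    --------
    >>> from leaf3d import LeafSegmenter
    >>> from leaf3d.phantom import PhantomSpec, generate_plant
    >>> cloud, truth = generate_plant(PhantomSpec(n_leaves=3, seed=7))
    >>> seg = LeafSegmenter(voxel_size_xy=0.1)
    >>> labels = seg.fit_predict(cloud)
    >>> seg.n_leaves_
    3
    """

    def __init__(
        self,
        green_threshold: float = 0.4,
        voxel_size_xy: float = 0.1,
        z_rebin_factor: float = 3.0,
        shrink_factor: float = 0.1,
        h_maxima: float = 0.1,
        marker_smooth_sigma: float = 1.0,
        mask_smooth_radius: int = 1,
        merge_seed_components: bool = True,
        plane_fit_radius_frac: float = 0.3,
        connectivity_3d: int = 26,
        connectivity_2d: int = 8,
        success_error_threshold: float = 0.10,
        method: str = "expand",
    ):
        self.green_threshold = green_threshold
        self.voxel_size_xy = voxel_size_xy
        self.z_rebin_factor = z_rebin_factor
        self.shrink_factor = shrink_factor
        self.h_maxima = h_maxima
        self.marker_smooth_sigma = marker_smooth_sigma
        self.mask_smooth_radius = mask_smooth_radius
        self.merge_seed_components = merge_seed_components
        self.plane_fit_radius_frac = plane_fit_radius_frac
        self.connectivity_3d = connectivity_3d
        self.connectivity_2d = connectivity_2d
        self.success_error_threshold = success_error_threshold
        self.method = method

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            green_threshold=self.green_threshold,
            voxel_size_xy=self.voxel_size_xy,
            z_rebin_factor=self.z_rebin_factor,
            shrink_factor=self.shrink_factor,
            h_maxima=self.h_maxima,
            marker_smooth_sigma=self.marker_smooth_sigma,
            mask_smooth_radius=self.mask_smooth_radius,
            merge_seed_components=self.merge_seed_components,
            plane_fit_radius_frac=self.plane_fit_radius_frac,
            connectivity_3d=self.connectivity_3d,
            connectivity_2d=self.connectivity_2d,
            success_error_threshold=self.success_error_threshold,
        )

    @staticmethod
    def _as_cloud(X) -> PointCloud:
        if isinstance(X, PointCloud):
            return X
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 6:
            raise ValueError(
                "X must be a PointCloud or an (n, 6) array of x,y,z,r,g,b rows"
            )
        return PointCloud(X[:, :3], X[:, 3:6].astype(np.uint8))

    def fit(self, X, y=None):
        """Segment the cloud; ``y`` is ignored (present for API parity)."""
        cloud = self._as_cloud(X)
        result = segment_plant(cloud, self._config(), method=self.method)
        self.result_ = result
        self.labels_ = result.labels
        self.grid_ = result.grid
        self.n_leaves_ = result.n_leaves
        self.n_features_in_ = 6
        return self

    def measure(self, X) -> "pd.DataFrame":  # noqa: F821
        """Traits table (area, inclination, centroid) of the fitted leaves.

        ``X`` must be the data the segmenter was fitted on.
        """
        check_is_fitted(self, "labels_")
        cloud = self._as_cloud(X).with_labels(self.labels_)
        return measure_leaves(
            cloud,
            voxel_size_xy=self.voxel_size_xy,
            z_rebin_factor=self.z_rebin_factor,
            plane_fit_radius_frac=self.plane_fit_radius_frac,
        )
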