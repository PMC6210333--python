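"""Pipeline configuration."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


@dataclass
class PipelineConfig:
    """All tunables of the segmentation + trait pipeline.

    Attributes
    ----------
    green_threshold : float
        Minimum normalized green value G/(R+G+B) for a point to count as
        leaf tissue; points strictly below are cut.  Default 0.4.
    voxel_size_xy : float
        Cubic voxel edge (cm) for segmentation.  Sensible range for small
        plants is about 0.03-0.2 cm, smaller for smaller plants.
    z_rebin_factor : float
        Z-voxel stretch used only for area estimation: the area grid is
        (s, s, z_rebin_factor * s), damping vertical surface noise.
    shrink_factor : float
        Per-leaf contraction of the initial 2D segmentation into a seed
        region (0.1 = reduce to one tenth about the centroid).
    h_maxima : float
        Depth (in pixels of distance) of the h-maxima suppression applied
        before taking watershed markers; 0 uses raw regional maxima.
    marker_smooth_sigma : float
        Gaussian sigma (pixels) applied to the distance map before marker
        detection; 0 disables smoothing.
    mask_smooth_radius : int
        Disc radius (pixels) of the morphological closing+opening that
        de-noises the top-view boundary before marker detection; 0
        disables it.
    plane_fit_radius_frac : float
        Fit neighborhood radius for inclination, as a fraction of the leaf
        bounding-box diagonal.
    merge_seed_components : bool
        Fuse seed regions that project into the same 3D connected
        component before growth: leaves the grower could not separate
        anyway must be fragments of one over-segmented leaf.  Lets
        ``h_maxima`` stay small (catching shallow saddles of deeply
        overlapped leaves) without over-segmenting elongated leaves.
    connectivity_3d : {6, 18, 26}
        Voxel adjacency used by region growing; 26 keeps obliquely
        voxelized leaf sheets connected.
    connectivity_2d : {4, 8}
        Pixel adjacency for the top-view foreground.
    success_error_threshold : float
        Relative area error below which a leaf counts as correctly
        segmented (strict <; default 0.10).
    random_seed : int
        Seed for any stochastic helper; the pipeline itself is
        deterministic.
    """

    green_threshold: float = 0.4
    voxel_size_xy: float = 0.1
    z_rebin_factor: float = 3.0
    shrink_factor: float = 0.1
    h_maxima: float = 0.1
    marker_smooth_sigma: float = 1.0
    mask_smooth_radius: int = 1
    plane_fit_radius_frac: float = 0.3
    merge_seed_components: bool = True
    connectivity_3d: int = 26
    connectivity_2d: int = 8
    success_error_threshold: float = 0.10
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("green_threshold", "shrink_factor",
                     "plane_fit_radius_frac", "success_error_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.voxel_size_xy <= 0:
            raise ValueError("voxel_size_xy must be positive")
        if self.z_rebin_factor <= 0:
            raise ValueError("z_rebin_factor must be positive")
        if self.connectivity_3d not in (6, 18, 26):
            raise ValueError("connectivity_3d must be 6, 18 or 26")
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")
        if self.h_maxima < 0:
            raise ValueError("h_maxima must be >= 0")
        if self.marker_smooth_sigma < 0:
            raise ValueError("marker_smooth_sigma must be >= 0")
        if self.mask_smooth_radius < 0:
            raise ValueError("mask_smooth_radius must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)
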