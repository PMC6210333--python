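"""Top-view seeding: projection, hole filling, distance transform,
watershed, and seed shrinkage.

The initial per-leaf segmentation works entirely in the top view: the
occupied voxels are flattened along Z into a binary mask, small sampling
holes are filled morphologically, and the Euclidean distance transform of
the foreground is partitioned by the watershed algorithm (markers at
distance maxima, one per leaf interior).  Each 2D leaf region is then
contracted about its centroid to a small seed that will be re-projected
into the 3D grid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, h_maxima, local_maxima, opening
from skimage.segmentation import watershed as _watershed

from .voxel import VoxelGrid, round_half_away

__all__ = [
    "project_topview",
    "fill_holes",
    "distance_map",
    "initial_segment",
    "shrink_seeds",
]


def project_topview(grid: VoxelGrid) -> np.ndarray:
    """Binary top-view mask: pixel (ix, iy) is 1 iff its vertical column
    contains at least one occupied voxel."""
    if not grid.occupancy.any():
        raise ValueError("grid has no occupied voxels; nothing to project")
    return grid.occupancy.any(axis=2).astype(np.uint8)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes of the foreground.

    A background component becomes foreground iff it is not 4-connected to
    the image border (the complementary convention to 8-connected
    foreground).  Filling only turns 0 into 1.
    """
    mask = np.asarray(mask).astype(bool)
    return ndimage.binary_fill_holes(mask).astype(np.uint8)


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance transform of the foreground.

    Each foreground pixel carries its distance to the nearest background
    pixel, so leaf interiors are bright and edges dark; background is 0.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.all():
        raise ValueError(
            "mask is entirely foreground: no background edge to measure from"
        )
    return ndimage.distance_transform_edt(mask)


def initial_segment(
    mask: np.ndarray,
    h: float = 0.1,
    connectivity: int = 8,
    smooth_sigma: float = 1.0,
    mask_smooth_radius: int = 1,
) -> np.ndarray:
    """Watershed segmentation of the top-view mask via its distance transform.

    Point-sampled masks have ragged single-pixel boundaries whose distance
    ridge carries spurious maxima — sometimes more prominent than the true
    saddle between a large leaf and a deeply overlapped small one, so no
    h-maxima depth alone can separate the two.  Markers are therefore
    computed on a boundary-smoothed copy of the mask (morphological
    closing then opening with a ``mask_smooth_radius``-px disc, which
    removes the raggedness at its source), whose distance transform is
    additionally Gaussian-smoothed by ``smooth_sigma`` pixels before
    h-maxima suppression with depth ``h``.  The watershed of the negated
    smoothed distance map is then flooded over the ORIGINAL foreground, so
    the labels always partition the input mask; any foreground component
    the smoothing erased entirely (isolated specks) receives its own label.
    ``h=0, smooth_sigma=0, mask_smooth_radius=0`` reproduces the naive
    reading: raw regional maxima of the exact distance map.

    Returns a 2D int32 label image, 0 = background, labels 1..K.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask has no foreground pixel")
    distance_map(mask)  # surfaces the all-foreground contract error

    work = mask
    if mask_smooth_radius > 0:
        footprint = disk(mask_smooth_radius)
        work = opening(closing(mask, footprint), footprint)
        if not work.any():  # structure thinner than the disc: fall back
            work = mask
    dist = ndimage.distance_transform_edt(work)
    if smooth_sigma > 0:
        dist = ndimage.gaussian_filter(dist, smooth_sigma)
        dist[~work] = 0.0
    if h > 0:
        peaks = h_maxima(dist, h) > 0
    else:
        peaks = local_maxima(dist)
    peaks &= work
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    markers, n_markers = ndimage.label(peaks, structure=structure)
    labels = _watershed(
        -dist, markers=markers, mask=mask,
        connectivity=2 if connectivity == 8 else 1,
    )
    leftover = mask & (labels == 0)
    if leftover.any():
        extra, _ = ndimage.label(leftover, structure=structure)
        labels = np.where(leftover, extra + n_markers, labels)
    return _relabel_consecutive(labels)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Renumber nonzero labels to consecutive 1..K (sorted order preserved)."""
    labels = np.asarray(labels)
    values = np.unique(labels)
    values = values[values != 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[values] = np.arange(1, len(values) + 1, dtype=np.int32)
    return lut[labels]


def shrink_seeds(labels: np.ndarray, shrink_factor: float = 0.1) -> np.ndarray:
    """Contract every label region about its own centroid.

    Pixel coordinates of each label are affinely scaled toward the label's
    centroid by ``shrink_factor`` and re-rasterized with nearest-pixel
    rounding (half away from zero).  Every label keeps at least one pixel:
    if contraction rasterizes to nothing — possible for thin regions — the
    pixel nearest the centroid is forced.  Seeds never grow beyond the
    original pixel count and never leave the label's bounding box.
    """
    if not 0.0 < shrink_factor <= 1.0:
        raise ValueError(f"shrink_factor must be in (0, 1], got {shrink_factor}")
    labels = np.asarray(labels)
    values = np.unique(labels)
    values = values[values != 0]
    if len(values) == 0:
        raise ValueError("label image has no labels to shrink")
    out = np.zeros_like(labels, dtype=np.int32)
    for val in values:  # ascending: earlier (smaller) labels keep contested pixels
        coords = np.argwhere(labels == val)
        centroid = coords.mean(axis=0)
        shrunk = round_half_away(centroid + shrink_factor * (coords - centroid))
        shrunk = np.unique(shrunk, axis=0)
        free = out[shrunk[:, 0], shrunk[:, 1]] == 0
        shrunk = shrunk[free]
        if len(shrunk) == 0:
            # thin region whose contraction rasterized to nothing (or to
            # pixels already claimed): force the label's own pixel nearest
            # its centroid, preferring an unclaimed one
            order = np.argsort(((coords - centroid) ** 2).sum(axis=1), kind="stable")
            ranked = coords[order]
            unclaimed = out[ranked[:, 0], ranked[:, 1]] == 0
            shrunk = ranked[unclaimed][:1] if unclaimed.any() else ranked[:1]
        out[shrunk[:, 0], shrunk[:, 1]] = val
    return out
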