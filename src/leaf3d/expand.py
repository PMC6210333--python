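"""Seeded 3D region growing on the voxel grid ("attribute expansion"),
plus the simple-projection baseline.

The 2D seeds are projected onto the topmost occupied voxel of each column
(the voxel actually visible in the top view), then each leaf number spreads
synchronously to adjacent occupied voxels until no voxel changes.  Growth
cannot cross empty space, so it stops at leaf edges and — unlike stamping
the 2D labels straight down each column — correctly reaches parts of lower
leaves occluded in the top view.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .voxel import VoxelGrid

__all__ = [
    "project_seeds",
    "merge_seeds_by_component",
    "relabel_consecutive",
    "expand_attributes",
    "simple_projection_segment",
    "neighbor_offsets",
]

_CONN_TO_RANK = {6: 1, 18: 2, 26: 3}


def neighbor_offsets(connectivity: int) -> np.ndarray:
    """The (k, 3) integer offsets of a 6/18/26-connected 3D neighborhood."""
    if connectivity not in _CONN_TO_RANK:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    struct = ndimage.generate_binary_structure(3, _CONN_TO_RANK[connectivity])
    offs = np.argwhere(struct) - 1
    return offs[np.any(offs != 0, axis=1)]


def project_seeds(seeds2d: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Project 2D seed labels onto the topmost occupied voxel per column.

    The seed image derives from the top view, so it can only speak for the
    surface visible from above: for each nonzero seed pixel the highest
    occupied voxel in that (ix, iy) column takes the pixel's leaf number.
    Columns without occupied voxels contribute nothing.

    Returns a 3D int32 label volume of seed voxels (0 elsewhere).
    """
    seeds2d = np.asarray(seeds2d)
    if seeds2d.shape != grid.shape[:2]:
        raise ValueError(
            f"seed image shape {seeds2d.shape} does not match grid X-Y shape {grid.shape[:2]}"
        )
    occ = grid.occupancy.astype(bool)
    nz = grid.shape[2]
    has_any = occ.any(axis=2)
    # topmost occupied index per column
    top = (nz - 1) - np.argmax(occ[:, :, ::-1], axis=2)
    seeded_cols = (seeds2d > 0) & has_any
    out = np.zeros(grid.shape, dtype=np.int32)
    ix, iy = np.nonzero(seeded_cols)
    out[ix, iy, top[ix, iy]] = seeds2d[ix, iy]
    if not out.any():
        raise ValueError("no seed pixel maps to an occupied voxel; cannot grow")
    return out


def merge_seeds_by_component(
    grid: VoxelGrid,
    seeds: np.ndarray,
    connectivity: int = 26,
) -> np.ndarray:
    """Fuse seed labels that landed on the same 3D connected component.

    The growth stage can only separate leaves that are distinct connected
    components of the occupied voxels — region expansion stops at leaf
    edges precisely because each leaf's edge is apart from other leaves in
    3D.  Under that same assumption, two seed regions inside one component
    must be fragments of a single over-segmented leaf, so every seed voxel
    of a component is relabeled to the smallest seed label present in that
    component.  Seeds on different components (e.g. two leaves overlapped
    in the top view but vertically separated) are never merged.

    Returns a new seed volume; labels are NOT renumbered here.
    """
    seeds = np.asarray(seeds, dtype=np.int32)
    if seeds.shape != grid.shape:
        raise ValueError("seeds volume shape must match the grid")
    rank = _CONN_TO_RANK.get(connectivity)
    if rank is None:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    struct = ndimage.generate_binary_structure(3, rank)
    comp, n_comp = ndimage.label(grid.occupancy.astype(bool), structure=struct)
    seeded = seeds > 0
    if not seeded.any():
        return seeds.copy()
    comp_of_seed = comp[seeded]
    label_of_seed = seeds[seeded]
    # smallest seed label per component
    min_label = np.full(n_comp + 1, np.iinfo(np.int32).max, dtype=np.int64)
    np.minimum.at(min_label, comp_of_seed, label_of_seed)
    out = seeds.copy()
    out[seeded] = min_label[comp_of_seed]
    return out


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Renumber nonzero labels to consecutive 1..K, preserving order."""
    labels = np.asarray(labels)
    values = np.unique(labels)
    values = values[values != 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[values] = np.arange(1, len(values) + 1, dtype=np.int32)
    return lut[labels]


def expand_attributes(
    grid: VoxelGrid,
    seeds: np.ndarray,
    connectivity: int = 26,
) -> tuple[VoxelGrid, int]:
    """Grow seed labels over the occupied voxels by synchronous rounds.

    At each round every unlabeled occupied voxel adjacent (under the given
    connectivity) to a labeled voxel takes that neighbor's label; when two
    labels reach a voxel in the same round the smaller leaf number wins, a
    deterministic, insertion-order-free rule.  Iteration stops when nothing
    changes.  Occupied voxels in connected components containing no seed
    stay 0 — they are counted and returned, never force-assigned.

    Returns ``(labeled_grid, n_unreached)``.
    """
    seeds = np.asarray(seeds, dtype=np.int32)
    if seeds.shape != grid.shape:
        raise ValueError("seeds volume shape must match the grid")
    occ = grid.occupancy.astype(bool)
    if not (seeds[occ] > 0).any():
        raise ValueError("no seed voxel on an occupied voxel")

    shape = np.array(grid.shape, dtype=np.int64)
    labels = np.where(occ, seeds, 0).astype(np.int32)
    flat_labels = labels.ravel()
    occ_flat = occ.ravel()
    offs = neighbor_offsets(connectivity)
    # flat-index strides for each neighbor offset
    strides = offs @ np.array(
        [shape[1] * shape[2], shape[2], 1], dtype=np.int64
    )

    frontier = np.flatnonzero(flat_labels > 0)
    fidx = np.array(np.unravel_index(frontier, grid.shape)).T
    while len(frontier):
        # candidate neighbors of the frontier, kept in-bounds per axis
        cand_idx = fidx[:, None, :] + offs[None, :, :]
        inb = np.all((cand_idx >= 0) & (cand_idx < shape), axis=2)
        src = np.repeat(np.arange(len(frontier)), offs.shape[0]).reshape(
            len(frontier), offs.shape[0]
        )
        flat_cand = (frontier[:, None] + strides[None, :])[inb]
        cand_labels = flat_labels[frontier[src[inb]]]
        take = occ_flat[flat_cand] & (flat_labels[flat_cand] == 0)
        flat_cand = flat_cand[take]
        cand_labels = cand_labels[take]
        if len(flat_cand) == 0:
            break
        # same-round conflicts: smallest leaf number wins
        order = np.lexsort((cand_labels, flat_cand))
        flat_cand = flat_cand[order]
        cand_labels = cand_labels[order]
        uniq, first = np.unique(flat_cand, return_index=True)
        flat_labels[uniq] = cand_labels[first]
        frontier = uniq
        fidx = np.array(np.unravel_index(frontier, grid.shape)).T

    labels = flat_labels.reshape(grid.shape)
    n_unreached = int(np.count_nonzero(occ & (labels == 0)))
    return (
        VoxelGrid(grid.origin, grid.voxel_size, grid.occupancy, labels),
        n_unreached,
    )


def simple_projection_segment(initial2d: np.ndarray, grid: VoxelGrid) -> VoxelGrid:
    """Baseline: stamp the 2D watershed labels down every voxel column.

    Every occupied voxel in column (ix, iy) takes label ``initial2d[ix, iy]``;
    voxels under background pixels stay 0.  This reproduces the known
    occlusion failure — a lower leaf hidden in the top view inherits the
    upper leaf's label or is missed entirely.
    """
    initial2d = np.asarray(initial2d)
    if initial2d.shape != grid.shape[:2]:
        raise ValueError("label image shape must match grid X-Y shape")
    labels = np.where(
        grid.occupancy.astype(bool), initial2d[:, :, None].astype(np.int32), 0
    )
    return VoxelGrid(grid.origin, grid.voxel_size, grid.occupancy, labels)
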