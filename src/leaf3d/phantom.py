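"""Synthetic plant phantoms with exact ground truth.

The generator emulates a small rosette plant as seen by a dense
photogrammetric reconstruction: each leaf is a planar (optionally gently
sagged) ellipse sampled uniformly at a surface density typical of
structure-from-motion clouds, tilted to a known inclination, jittered
along its normal by isotropic surface noise, and colored green.  Leaves
are arranged on a ring so that, apart from one optional designated
overlapped pair, every pair of leaves keeps a clear 3D gap.  The
designated pair is stacked with a controlled top-view footprint overlap
and a vertical gap of a few voxels — the configuration where naive
top-view projection fails but 3D growth succeeds.  Optional non-green
"branch" clutter exercises the green filter.

Every leaf's planar area (pi*a*b), inclination angle and per-point label
are known exactly, so segmentation and trait estimates can be scored
against analytic truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cloud import PointCloud
from .traits import leaf_area

__all__ = ["PhantomSpec", "PhantomTruth", "generate_leaf", "generate_plant"]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic plant.

    Leaves are ellipses with semi-major axis ``a`` drawn uniformly from
    ``semi_axis_range`` (cm) and ``b = aspect * a``; inclinations are drawn
    uniformly from ``inclination_range`` (degrees).  ``overlap > 0``
    designates leaves 1 and 2 as a stacked pair whose top-view footprints
    intersect by that fraction of the smaller footprint, separated
    vertically by ``vertical_gap_voxels`` voxels at the stated grid.
    ``points_per_cm2`` reflects a dense SfM reconstruction; ``noise_sigma``
    is the 1-sigma surface jitter (cm) along the local normal.
    """

    n_leaves: int = 5
    semi_axis_range: tuple[float, float] = (2.0, 4.0)
    aspect: float = 0.6
    inclination_range: tuple[float, float] = (10.0, 60.0)
    curvature: float = 0.0
    points_per_cm2: float = 250.0
    noise_sigma: float = 0.02
    overlap: float = 0.0
    vertical_gap_voxels: float = 3.0
    clutter: bool = False
    voxel_size_xy: float = 0.1
    z_rebin_factor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.points_per_cm2 <= 0:
            raise ValueError("points_per_cm2 must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.overlap > 0 and self.n_leaves < 2:
            raise ValueError("an overlapped pair needs at least 2 leaves")


@dataclass
class PhantomTruth:
    """Ground truth for a phantom: per-point labels and a per-leaf table
    with planar area (cm²), inclination (deg), and the voxel-count area at
    the stated (s, s, z_rebin*s) grid."""

    point_labels: np.ndarray
    leaves: pd.DataFrame = field(repr=False)


def _leaf_points_local(
    a: float,
    b: float,
    curvature: float,
    n_points: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform sample of the (optionally sagged) ellipse in its own frame."""
    u = rng.uniform(0.0, 1.0, n_points)
    t = rng.uniform(0.0, 2.0 * np.pi, n_points)
    x = a * np.sqrt(u) * np.cos(t)
    y = b * np.sqrt(u) * np.sin(t)
    # parabolic sag: drops to -curvature*a at the rim
    z = -curvature * a * ((x / a) ** 2 + (y / b) ** 2)
    return np.column_stack([x, y, z])


def _pose(points: np.ndarray, inclination_deg: float, azimuth_deg: float,
          centroid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a local leaf into the world: tilt about Y, spin about Z,
    translate.  Returns (points, unit normal)."""
    th = np.radians(inclination_deg)
    az = np.radians(azimuth_deg)
    ry = np.array([[np.cos(th), 0, np.sin(th)],
                   [0, 1, 0],
                   [-np.sin(th), 0, np.cos(th)]])
    rz = np.array([[np.cos(az), -np.sin(az), 0],
                   [np.sin(az), np.cos(az), 0],
                   [0, 0, 1]])
    rot = rz @ ry
    normal = rot @ np.array([0.0, 0.0, 1.0])
    return points @ rot.T + centroid, normal


def _green_colors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Leaf-like green RGB with G/(R+G+B) safely above 0.4."""
    r = rng.integers(10, 60, n)
    g = rng.integers(130, 220, n)
    b = rng.integers(10, 60, n)
    return np.column_stack([r, g, b]).astype(np.uint8)


def generate_leaf(
    a: float,
    b: float,
    inclination_deg: float,
    azimuth_deg: float = 0.0,
    centroid=(0.0, 0.0, 0.0),
    curvature: float = 0.0,
    points_per_cm2: float = 250.0,
    noise_sigma: float = 0.02,
    rng: np.random.Generator | None = None,
    label: int = 1,
) -> tuple[PointCloud, dict]:
    """Generate one leaf and its ground-truth row.

    Points are sampled uniformly on the ellipse, posed, and jittered by
    ``noise_sigma`` along the leaf normal.  The truth row records the
    planar area ``pi*a*b`` (exact for curvature 0; for sagged leaves it is
    the area of the generating ellipse) and the generating inclination.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    centroid = np.asarray(centroid, dtype=np.float64)
    n_points = max(int(round(points_per_cm2 * np.pi * a * b)), 50)
    local = _leaf_points_local(a, b, curvature, n_points, rng)
    pts, normal = _pose(local, inclination_deg, azimuth_deg, centroid)
    if noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, n_points)[:, None] * normal
    cloud = PointCloud(
        pts, _green_colors(n_points, rng), np.full(n_points, label, dtype=np.int64)
    )
    truth = {
        "leaf_number": label,
        "planar_area_cm2": np.pi * a * b,
        "inclination_deg": float(inclination_deg),
        "semi_axis_a": a,
        "semi_axis_b": b,
    }
    return cloud, truth


def _footprint_overlap(pts_a: np.ndarray, pts_b: np.ndarray, s: float) -> float:
    """Top-view footprint intersection over the smaller footprint, measured
    on rasterized (s-sized) pixels."""
    cells_a = {tuple(c) for c in np.floor(pts_a[:, :2] / s).astype(int)}
    cells_b = {tuple(c) for c in np.floor(pts_b[:, :2] / s).astype(int)}
    inter = len(cells_a & cells_b)
    return inter / min(len(cells_a), len(cells_b))


def _clutter_points(center: np.ndarray, z_range: tuple[float, float],
                    rng: np.random.Generator) -> PointCloud:
    """A brown vertical 'branch' at the plant centre (non-green clutter)."""
    n = 1500
    z = rng.uniform(z_range[0], z_range[1], n)
    r = rng.uniform(0.0, 0.2, n)
    t = rng.uniform(0.0, 2 * np.pi, n)
    pts = np.column_stack([center[0] + r * np.cos(t),
                           center[1] + r * np.sin(t), z])
    colors = np.tile(np.array([101, 67, 33], dtype=np.uint8), (n, 1))
    return PointCloud(pts, colors, np.zeros(n, dtype=np.int64))


def generate_plant(spec: PhantomSpec) -> tuple[PointCloud, PhantomTruth]:
    """Generate a whole phantom plant with exact ground truth.

    Leaves (or the designated overlapped pair, treated as one placement
    unit) sit on a ring whose radius is grown until every non-pair leaf
    pair keeps a 3D gap of at least ~3 voxels; heights are staggered.  For
    the pair, the horizontal offset is found by bisection so that the
    rasterized footprint overlap hits ``spec.overlap`` within +-0.02, and
    the vertical offset leaves ``vertical_gap_voxels`` empty voxels
    between the two leaves.  All randomness flows through one generator
    seeded by ``spec.seed``: identical spec implies an identical phantom.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.voxel_size_xy
    n = spec.n_leaves

    a_lo, a_hi = spec.semi_axis_range
    axes = rng.uniform(a_lo, a_hi, n)
    inc_lo, inc_hi = spec.inclination_range
    inclinations = rng.uniform(inc_lo, inc_hi, n)

    pair = spec.overlap > 0.0
    if pair:
        # stacked leaves must stay footprint-fat: cap the pair's tilt
        inclinations[:2] = rng.uniform(5.0, min(20.0, inc_hi), 2)

    # generate every leaf in local pose (centroid at origin)
    leaf_clouds: list[PointCloud] = []
    truth_rows: list[dict] = []
    for i in range(n):
        azim = 0.0 if (pair and i < 2) else float(rng.uniform(0.0, 360.0))
        cloud, row = generate_leaf(
            a=float(axes[i]), b=float(spec.aspect * axes[i]),
            inclination_deg=float(inclinations[i]), azimuth_deg=azim,
            centroid=(0.0, 0.0, 0.0), curvature=spec.curvature,
            points_per_cm2=spec.points_per_cm2, noise_sigma=spec.noise_sigma,
            rng=rng, label=i + 1,
        )
        leaf_clouds.append(cloud)
        truth_rows.append(row)

    # ---- assemble placement units -------------------------------------
    if pair:
        lower, upper = leaf_clouds[0].points, leaf_clouds[1].points
        dz = (lower[:, 2].max() - upper[:, 2].min()
              + spec.vertical_gap_voxels * s + s)
        target = spec.overlap

        def measured(dx: float) -> float:
            return _footprint_overlap(lower, upper + np.array([dx, 0.0, dz]), s)

        lo_dx, hi_dx = 0.0, float(2.0 * (axes[0] + axes[1]))
        for _ in range(50):
            mid = 0.5 * (lo_dx + hi_dx)
            if measured(mid) > target:
                lo_dx = mid
            else:
                hi_dx = mid
        dx = 0.5 * (lo_dx + hi_dx)
        got = measured(dx)
        if abs(got - target) > 0.05 * max(target, 1e-9) + 0.02:
            raise RuntimeError(
                f"could not reach footprint overlap {target:.2f} (got {got:.2f}); "
                "try smaller overlap or fewer leaves"
            )
        pair_offset = np.array([dx, 0.0, dz])
        units: list[list[int]] = [[0, 1]] + [[i] for i in range(2, n)]
        offsets_in_unit = {0: np.zeros(3), 1: pair_offset}
    else:
        units = [[i] for i in range(n)]
        offsets_in_unit = {i: np.zeros(3) for i in range(n)}

    # ---- place units on a ring, growing it until gaps are honoured -----
    m = len(units)
    angles = 2.0 * np.pi * np.arange(m) / m
    half_widths = []
    for unit in units:
        pts = np.vstack([leaf_clouds[i].points
                         + offsets_in_unit.get(i, np.zeros(3))
                         for i in unit])
        half_widths.append(np.linalg.norm(pts[:, :2], axis=1).max())
    clearance = 5.0 * s
    if m == 1:
        radius = 0.0
    else:
        need = max(half_widths[k] + half_widths[(k + 1) % m] + clearance
                   for k in range(m))
        radius = need / (2.0 * np.sin(np.pi / m))
    z_step = 1.0  # cm of height stagger between units

    min_gap = (spec.vertical_gap_voxels - 1.0) * s  # ~>= 2 voxels of air

    for _attempt in range(8):
        placed = [None] * n
        for k, unit in enumerate(units):
            base = np.array([radius * np.cos(angles[k]),
                             radius * np.sin(angles[k]),
                             k * z_step])
            for i in unit:
                placed[i] = (leaf_clouds[i].points
                             + offsets_in_unit.get(i, np.zeros(3)) + base)
        trees = [cKDTree(p) for p in placed]
        ok = True
        for i in range(n):
            for j in range(i + 1, n):
                if pair and {i, j} == {0, 1}:
                    continue
                d = trees[i].query(placed[j], k=1)[0].min()
                if d < max(min_gap, 3.0 * s):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            break
        radius *= 1.3
    else:
        raise RuntimeError(
            "could not place leaves with the required 3D gaps; "
            "try fewer leaves or a smaller overlap"
        )

    all_points = np.vstack(placed)
    all_colors = np.vstack([c.colors for c in leaf_clouds])
    all_labels = np.concatenate([c.labels for c in leaf_clouds])

    if spec.clutter:
        zr = (all_points[:, 2].min() - 1.0, all_points[:, 2].max())
        clutter = _clutter_points(np.zeros(3), zr, rng)
        all_points = np.vstack([all_points, clutter.points])
        all_colors = np.vstack([all_colors, clutter.colors])
        all_labels = np.concatenate([all_labels, clutter.labels])

    cloud = PointCloud(all_points, all_colors, all_labels)

    # per-leaf voxel-count area at the stated grid, from true labels
    leaves = pd.DataFrame(truth_rows)
    leaves["voxel_area_cm2"] = [
        leaf_area(cloud, int(l), s, spec.z_rebin_factor)
        for l in leaves["leaf_number"]
    ]
    leaves["voxel_count"] = (leaves["voxel_area_cm2"] / (s * s)).round().astype(int)
    return cloud, PhantomTruth(point_labels=all_labels.copy(), leaves=leaves)
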