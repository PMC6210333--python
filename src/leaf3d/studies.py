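"""Benchmark studies on phantom plants.

Each study generates a fresh batch of phantoms, runs the full pipeline on
them, and reports the aggregate accuracy the field cares about: plane-fit
inclination RMSE, voxel-count area MAPE, the <10%-area-error segmentation
success rate, and the paired benefit of 3D growth over simple projection
on top-view-overlapped leaves.  All randomness in a study flows from its
single ``seed``.
"""

from __future__ import annotations

import numpy as np

from .cloud import PointCloud
from .config import PipelineConfig
from .evaluate import (
    compare_methods,
    evaluate_plant,
    match_leaves,
    success_rate,
)
from .phantom import PhantomSpec, generate_leaf, generate_plant, PhantomTruth
from .pipeline import segment_plant
from .traits import leaf_area, leaf_inclination

__all__ = [
    "inclination_study",
    "area_study",
    "segmentation_success_study",
    "overlap_benefit_study",
]


def _single_leaf_phantom(a: float, inclination: float, noise_sigma: float,
                         rng: np.random.Generator):
    cloud, row = generate_leaf(
        a=a, b=a, inclination_deg=inclination,
        azimuth_deg=float(rng.uniform(0, 360)),
        points_per_cm2=250.0, noise_sigma=noise_sigma, rng=rng, label=1,
    )
    return cloud, row


def inclination_study(
    n_leaves: int = 30,
    angle_range: tuple[float, float] = (0.0, 80.0),
    semi_axis_range: tuple[float, float] = (2.0, 5.0),
    noise_frac_of_diameter: float = 0.01,
    seed: int = 42,
    config: PipelineConfig | None = None,
) -> dict:
    """Inclination recovery on single-leaf phantoms after full segmentation.

    Circular leaves (radius 2-5 cm), angles uniform over ``angle_range``,
    surface noise sigma = ``noise_frac_of_diameter`` x leaf diameter.  Each
    leaf runs through the complete pipeline (filter, voxelize, seed, grow)
    before the plane fit.  Returns per-leaf angles and their RMSE (deg).
    """
    rng = np.random.default_rng(seed)
    config = config or PipelineConfig()
    true_angles, est_angles = [], []
    for _ in range(n_leaves):
        a = float(rng.uniform(*semi_axis_range))
        angle = float(rng.uniform(*angle_range))
        cloud, _ = _single_leaf_phantom(a, angle, noise_frac_of_diameter * 2 * a, rng)
        result = segment_plant(cloud, config)
        est_cloud = cloud.with_labels(result.labels)
        pairing, _, _ = match_leaves(result.labels, cloud.labels)
        est_label = next(e for e, t in pairing.items() if t == 1)
        est_angles.append(leaf_inclination(est_cloud, est_label,
                                           config.plane_fit_radius_frac))
        true_angles.append(angle)
    resid = np.array(est_angles) - np.array(true_angles)
    return {
        "rmse_deg": float(np.sqrt(np.mean(resid**2))),
        "mean_abs_error_deg": float(np.abs(resid).mean()),
        "true_deg": true_angles,
        "est_deg": est_angles,
        "n": n_leaves,
    }


def area_study(
    n_leaves: int = 30,
    area_range: tuple[float, float] = (8.0, 75.0),
    angle_range: tuple[float, float] = (0.0, 60.0),
    noise_sigma: float = 0.02,
    seed: int = 42,
    config: PipelineConfig | None = None,
) -> dict:
    """Area recovery on separated single-leaf phantoms.

    Leaf planar areas are drawn uniformly over ``area_range`` (cm², the
    span of small ornamental plants).  Each leaf is segmented by the full
    pipeline; the estimated voxel-count area is scored against the
    voxel-count area of the true labels at the same grid.  Returns per-leaf
    areas and the MAPE (%).
    """
    rng = np.random.default_rng(seed)
    config = config or PipelineConfig()
    true_areas, est_areas = [], []
    for _ in range(n_leaves):
        area = float(rng.uniform(*area_range))
        a = float(np.sqrt(area / np.pi))
        angle = float(rng.uniform(*angle_range))
        cloud, _ = _single_leaf_phantom(a, angle, noise_sigma, rng)
        result = segment_plant(cloud, config)
        est_cloud = cloud.with_labels(result.labels)
        pairing, _, _ = match_leaves(result.labels, cloud.labels)
        est_label = next(e for e, t in pairing.items() if t == 1)
        est_areas.append(leaf_area(est_cloud, est_label,
                                   config.voxel_size_xy, config.z_rebin_factor))
        true_areas.append(leaf_area(cloud, 1,
                                    config.voxel_size_xy, config.z_rebin_factor))
    ape = 100.0 * np.abs(np.array(est_areas) - np.array(true_areas)) / np.array(true_areas)
    return {
        "mape_pct": float(ape.mean()),
        "true_area_cm2": true_areas,
        "est_area_cm2": est_areas,
        "n": n_leaves,
    }


def segmentation_success_study(
    n_plants: int = 10,
    leaves_range: tuple[int, int] = (4, 11),
    overlap: float = 0.2,
    seed: int = 123,
    config: PipelineConfig | None = None,
) -> dict:
    """Segmentation success rate over multi-leaf plants with one
    moderately overlapped pair each.

    Each plant has 4-11 leaves; one designated pair overlaps in the top
    view by ``overlap`` with a 3-voxel vertical gap.  A leaf counts as
    correctly segmented iff its voxel-count area error is strictly below
    10%; true leaves the segmentation missed count as failures.  The rate
    is pooled over all leaves of all plants.
    """
    rng = np.random.default_rng(seed)
    config = config or PipelineConfig()
    errors: list[float] = []
    n_leaves_total = 0
    per_plant = []
    for _ in range(n_plants):
        n_leaves = int(rng.integers(leaves_range[0], leaves_range[1] + 1))
        spec = PhantomSpec(
            n_leaves=n_leaves, overlap=overlap,
            vertical_gap_voxels=3.0, seed=int(rng.integers(2**31)),
        )
        cloud, truth = generate_plant(spec)
        report = evaluate_plant(cloud, truth, config)
        plant_errors = report.per_leaf["area_rel_error"].tolist()
        plant_errors += [float("inf")] * report.n_unmatched_true
        errors.extend(plant_errors)
        n_leaves_total += report.n_leaves_true
        per_plant.append({"n_leaves": n_leaves,
                          "success_pct": report.success_rate_pct})
    return {
        "success_rate_pct": success_rate(errors, config.success_error_threshold),
        "n_leaves": n_leaves_total,
        "n_plants": n_plants,
        "per_plant": per_plant,
    }


def overlap_benefit_study(
    n_pairs: int = 10,
    overlap: float = 0.3,
    seed: int = 99,
    config: PipelineConfig | None = None,
) -> dict:
    """Paired comparison of 3D growth vs simple projection on two-leaf
    phantoms overlapped in the top view (3-voxel vertical gap).

    Reports the pooled per-leaf area MAPE of each method over all
    2 x n_pairs leaves and the exact paired sign-flip permutation p-value
    of the per-pair difference.
    """
    rng = np.random.default_rng(seed)
    config = config or PipelineConfig()
    phantoms: list[tuple[PointCloud, PhantomTruth]] = []
    for _ in range(n_pairs):
        spec = PhantomSpec(
            n_leaves=2, overlap=overlap, vertical_gap_voxels=3.0,
            seed=int(rng.integers(2**31)),
        )
        phantoms.append(generate_plant(spec))
    out = compare_methods(phantoms, config)
    out["overlap"] = overlap
    return out
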