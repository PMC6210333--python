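"""Evaluation of segmentation and trait estimates against ground truth:
leaf matching, the <10%-area-error success rate, RMSE/MAPE/R², and the
paired comparison between the 3D-growth method and the simple-projection
baseline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .cloud import PointCloud
from .config import PipelineConfig
from .phantom import PhantomTruth
from .pipeline import segment_plant
from .traits import leaf_area, leaf_inclination

__all__ = [
    "match_leaves",
    "success_rate",
    "accuracy_stats",
    "EvalReport",
    "evaluate_plant",
    "compare_methods",
    "paired_sign_flip_test",
]


def match_leaves(
    est_labels: np.ndarray, true_labels: np.ndarray
) -> tuple[dict[int, int], list[int], list[int]]:
    """Greedy maximum-overlap matching between estimated and true leaves.

    Both arrays are integer labelings of the same cells (voxels or points);
    0 means unassigned and never matches.  Pairs are taken in order of
    shared-cell count (ties broken by smaller estimated, then true label),
    each side used at most once.

    Returns ``(pairing, unmatched_est, unmatched_true)`` where ``pairing``
    maps estimated label -> true label.
    """
    est = np.asarray(est_labels).ravel()
    tru = np.asarray(true_labels).ravel()
    if est.shape != tru.shape:
        raise ValueError("labelings must have the same shape")
    both = (est > 0) & (tru > 0)
    if not both.any() and not (est > 0).any() and not (tru > 0).any():
        raise ValueError("both labelings are empty")
    pairs, counts = np.unique(
        np.column_stack([est[both], tru[both]]), axis=0, return_counts=True
    ) if both.any() else (np.empty((0, 2), dtype=int), np.empty(0, dtype=int))
    order = np.lexsort((pairs[:, 1], pairs[:, 0], -counts))
    pairing: dict[int, int] = {}
    used_true: set[int] = set()
    for k in order:
        e, t = int(pairs[k, 0]), int(pairs[k, 1])
        if e in pairing or t in used_true:
            continue
        pairing[e] = t
        used_true.add(t)
    est_all = set(np.unique(est[est > 0]).tolist())
    true_all = set(np.unique(tru[tru > 0]).tolist())
    unmatched_est = sorted(est_all - set(pairing))
    unmatched_true = sorted(true_all - used_true)
    return pairing, unmatched_est, unmatched_true


def success_rate(pct_errors, threshold: float = 0.10) -> float:
    """Percentage of leaves segmented correctly.

    A leaf counts as correct iff its relative area error is STRICTLY below
    ``threshold`` (an error of exactly the threshold is a failure).
    Unmatched leaves are passed as ``inf`` so they count as failures.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    errors = np.asarray(list(pct_errors), dtype=np.float64)
    if errors.size == 0:
        raise ValueError("no leaves to score")
    return 100.0 * float(np.count_nonzero(errors < threshold)) / errors.size


def accuracy_stats(true_vals, est_vals) -> dict:
    """RMSE, MAPE (mean ± sample sd of per-leaf absolute percent errors),
    and the coefficient of determination R² of est against true.

    Pairs whose true value is 0 are excluded from MAPE (percent error is
    undefined there) and their count reported as ``n_mape_excluded``.
    """
    t = np.asarray(list(true_vals), dtype=np.float64)
    e = np.asarray(list(est_vals), dtype=np.float64)
    if t.shape != e.shape or t.size < 2:
        raise ValueError("need equal-length sequences of at least 2 values")
    resid = e - t
    rmse = float(np.sqrt(np.mean(resid**2)))
    nz = t != 0
    ape = 100.0 * np.abs(resid[nz]) / np.abs(t[nz])
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return {
        "rmse": rmse,
        "mape_mean": float(ape.mean()) if ape.size else float("nan"),
        "mape_sd": float(ape.std(ddof=1)) if ape.size > 1 else float("nan"),
        "r2": r2,
        "n": int(t.size),
        "n_mape_excluded": int(np.count_nonzero(~nz)),
    }


@dataclass
class EvalReport:
    """Per-leaf and aggregate evaluation of one segmented phantom."""

    per_leaf: pd.DataFrame = field(repr=False)
    success_rate_pct: float = float("nan")
    area_stats: dict = field(default_factory=dict)
    angle_stats: dict = field(default_factory=dict)
    n_leaves_true: int = 0
    n_leaves_est: int = 0
    n_unmatched_true: int = 0

    def to_json(self, **kwargs) -> str:
        payload = {
            "success_rate_pct": self.success_rate_pct,
            "area_stats": self.area_stats,
            "angle_stats": self.angle_stats,
            "n_leaves_true": self.n_leaves_true,
            "n_leaves_est": self.n_leaves_est,
            "n_unmatched_true": self.n_unmatched_true,
            "per_leaf": self.per_leaf.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, **kwargs)


def evaluate_plant(
    cloud: PointCloud,
    truth: PhantomTruth,
    config: PipelineConfig | None = None,
    method: str = "expand",
) -> EvalReport:
    """Run the pipeline on a phantom and score it against its truth.

    Leaves are matched by point overlap; per matched leaf the estimated
    voxel-count area is compared with the truth-label voxel-count area at
    the same grid, and the estimated inclination with the generating
    angle.  Unmatched true leaves enter the success rate as failures.
    """
    config = config or PipelineConfig()
    result = segment_plant(cloud, config, method=method)
    est = result.labels
    pairing, _, unmatched_true = match_leaves(est, truth.point_labels)

    est_cloud = cloud.with_labels(est)
    leaves = truth.leaves.set_index("leaf_number")
    rows = []
    for e_label, t_label in sorted(pairing.items()):
        true_area = float(leaves.loc[t_label, "voxel_area_cm2"])
        true_angle = float(leaves.loc[t_label, "inclination_deg"])
        est_area = leaf_area(
            est_cloud, e_label, config.voxel_size_xy, config.z_rebin_factor
        )
        try:
            est_angle = leaf_inclination(
                est_cloud, e_label, config.plane_fit_radius_frac
            )
        except ValueError:
            est_angle = float("nan")
        rel_err = abs(est_area - true_area) / true_area if true_area else float("inf")
        rows.append(
            {
                "true_leaf": t_label,
                "est_leaf": e_label,
                "true_area_cm2": true_area,
                "est_area_cm2": est_area,
                "area_rel_error": rel_err,
                "true_inclination_deg": true_angle,
                "est_inclination_deg": est_angle,
            }
        )
    per_leaf = pd.DataFrame(
        rows,
        columns=[
            "true_leaf", "est_leaf", "true_area_cm2", "est_area_cm2",
            "area_rel_error", "true_inclination_deg", "est_inclination_deg",
        ],
    )

    errors = per_leaf["area_rel_error"].tolist() + [float("inf")] * len(unmatched_true)
    sr = success_rate(errors, config.success_error_threshold)
    area_stats = (
        accuracy_stats(per_leaf["true_area_cm2"], per_leaf["est_area_cm2"])
        if len(per_leaf) >= 2 else {}
    )
    ok_angle = per_leaf["est_inclination_deg"].notna()
    angle_stats = (
        accuracy_stats(
            per_leaf.loc[ok_angle, "true_inclination_deg"],
            per_leaf.loc[ok_angle, "est_inclination_deg"],
        )
        if ok_angle.sum() >= 2 else {}
    )
    n_true = int((truth.leaves["leaf_number"] > 0).sum())
    return EvalReport(
        per_leaf=per_leaf,
        success_rate_pct=sr,
        area_stats=area_stats,
        angle_stats=angle_stats,
        n_leaves_true=n_true,
        n_leaves_est=int(np.unique(est[est > 0]).size),
        n_unmatched_true=len(unmatched_true),
    )


def paired_sign_flip_test(diffs) -> float:
    """Exact two-sided paired permutation test on the mean difference.

    Under the null of no method difference each pair's difference is
    symmetric around 0, so all 2^n sign assignments are equally likely;
    the p-value is the fraction with |mean| >= |observed mean|.
    """
    d = np.asarray(list(diffs), dtype=np.float64)
    n = d.size
    if n == 0:
        raise ValueError("no paired differences")
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20 pairs")
    observed = abs(d.mean())
    signs = np.array(list(product([-1.0, 1.0], repeat=n)))
    means = np.abs(signs @ d) / n
    return float(np.count_nonzero(means >= observed - 1e-12) / len(signs))


def compare_methods(
    phantoms: list[tuple[PointCloud, PhantomTruth]],
    config: PipelineConfig | None = None,
) -> dict:
    """Run 3D growth and simple projection on identical phantoms and
    compare their per-phantom area MAPEs with an exact paired sign-flip
    permutation test.

    Returns a dict with per-phantom MAPEs for both methods, their means,
    and the two-sided p-value.
    """
    if len(phantoms) < 2:
        raise ValueError("need at least 2 phantoms to compare methods")
    config = config or PipelineConfig()
    expand_mapes, simple_mapes = [], []
    for cloud, truth in phantoms:
        per_method = {}
        for method in ("expand", "simple"):
            report = evaluate_plant(cloud, truth, config, method=method)
            per = report.per_leaf
            matched_ape = (100.0 * per["area_rel_error"]).tolist()
            # true leaves the method missed entirely contribute 100% error
            matched_ape += [100.0] * report.n_unmatched_true
            per_method[method] = float(np.mean(matched_ape))
        expand_mapes.append(per_method["expand"])
        simple_mapes.append(per_method["simple"])
    diffs = np.array(simple_mapes) - np.array(expand_mapes)
    return {
        "expand_mape": expand_mapes,
        "simple_mape": simple_mapes,
        "expand_mape_mean": float(np.mean(expand_mapes)),
        "simple_mape_mean": float(np.mean(simple_mapes)),
        "p_value": paired_sign_flip_test(diffs),
        "n_pairs": len(phantoms),
    }
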