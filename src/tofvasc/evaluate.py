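"""Phantom-truth metrics and group-level descriptive summaries.

Overlap and centerline metrics quantify how well the pipeline recovers a
phantom's known vasculature: Dice on the vessel mask, tolerance-based
precision/recall on centerlines, trunk overlap, and a branch-level
confusion matrix (levels >= 3 collapsed, mirroring the QA color
taxonomy).  Distances are physical (mm), via Euclidean distance
transforms with the grid spacing as sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .grids import BinaryMask, BranchLabelVolume, require_same_grid

#: default match tolerance: 2x the largest voxel dimension of the
#: FLASH-TOF geometry (one-voxel skeleton jitter is expected from thinning)
DEFAULT_TOLERANCE_MM = 1.0


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    require_same_grid(a, b, "masks")
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def _distance_to(mask: BinaryMask) -> np.ndarray:
    """Physical distance (mm) from every voxel to the nearest True voxel."""
    return ndimage.distance_transform_edt(~mask.data, sampling=mask.spacing)


def centerline_precision_recall(
    pred_skeleton: BinaryMask, true_centerline: BinaryMask, tolerance_mm: float = DEFAULT_TOLERANCE_MM
) -> tuple[float, float]:
    """Fraction of predicted voxels near truth (precision) and of true
    voxels near the prediction (recall), at a physical tolerance."""
    require_same_grid(pred_skeleton, true_centerline, "skeleton and centerline")
    if tolerance_mm < 0:
        raise ValidationError("tolerance must be >= 0")
    if true_centerline.n_voxels == 0:
        raise ValidationError("true centerline is empty")
    if pred_skeleton.n_voxels == 0:
        return float("nan"), 0.0  # undefined precision flagged as NaN
    d_true = _distance_to(true_centerline)
    precision = float(np.mean(d_true[pred_skeleton.data] <= tolerance_mm))
    d_pred = _distance_to(pred_skeleton)
    recall = float(np.mean(d_pred[true_centerline.data] <= tolerance_mm))
    return precision, recall


def _collapse(levels: np.ndarray) -> np.ndarray:
    return np.minimum(levels, 3)


@dataclass
class MetricsReport:
    """All rates in [0,1]; confusion rows sum to matched voxels per true level."""

    dice: float = float("nan")
    centerline_precision: float = float("nan")
    centerline_recall: float = float("nan")
    trunk_overlap: float = float("nan")
    level_confusion: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=int))
    level_accuracy: float = float("nan")
    n_matched: int = 0
    n_unmatched: int = 0
    tolerance_mm: float = DEFAULT_TOLERANCE_MM

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "centerline_precision": self.centerline_precision,
            "centerline_recall": self.centerline_recall,
            "trunk_overlap": self.trunk_overlap,
            "level_confusion": self.level_confusion.tolist(),
            "level_accuracy": self.level_accuracy,
            "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched,
            "tolerance_mm": self.tolerance_mm,
        }


def branch_level_agreement(
    pred: BranchLabelVolume,
    truth: BranchLabelVolume,
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
) -> MetricsReport:
    """Match predicted skeleton voxels to nearest true centerline voxels and
    compare branch levels (>= 3 collapsed).

    trunk_overlap is the recall of true level-0 voxels by predicted
    level-0 at the tolerance.
    """
    if pred.shape != truth.shape or not np.allclose(pred.spacing, truth.spacing):
        raise ValidationError("label volumes must share a grid")
    truth_mask = truth.data >= 0
    if not truth_mask.any():
        raise ValidationError("truth label volume is empty")
    report = MetricsReport(tolerance_mm=tolerance_mm)
    pred_mask = pred.data >= 0
    if not pred_mask.any():
        report.n_unmatched = 0
        return report
    # nearest true centerline voxel for every grid voxel (EDT feature
    # transform; scipy returns the closest feature with deterministic ties)
    dist, (ix, iy, iz) = ndimage.distance_transform_edt(
        ~truth_mask, sampling=truth.spacing, return_indices=True
    )
    pred_idx = np.argwhere(pred_mask)
    px, py, pz = pred_idx[:, 0], pred_idx[:, 1], pred_idx[:, 2]
    d = dist[px, py, pz]
    matched = d <= tolerance_mm
    report.n_matched = int(matched.sum())
    report.n_unmatched = int((~matched).sum())
    if report.n_matched == 0:
        return report
    mx, my, mz = px[matched], py[matched], pz[matched]
    pred_lv = _collapse(pred.data[mx, my, mz].astype(int))
    true_lv = _collapse(truth.data[ix[mx, my, mz], iy[mx, my, mz], iz[mx, my, mz]].astype(int))
    conf = np.zeros((4, 4), dtype=int)
    np.add.at(conf, (true_lv, pred_lv), 1)
    report.level_confusion = conf
    report.level_accuracy = float(np.trace(conf) / conf.sum())
    # trunk overlap: true level-0 voxels within tolerance of predicted level-0
    true0 = BinaryMask(truth.data == 0, truth.spacing, truth.affine)
    pred0 = BinaryMask(pred.data == 0, pred.spacing, pred.affine)
    if pred0.n_voxels == 0:
        report.trunk_overlap = 0.0
    else:
        d_pred0 = _distance_to(pred0)
        report.trunk_overlap = float(np.mean(d_pred0[true0.data] <= tolerance_mm))
    return report


def evaluate_against_truth(
    vessel_mask: BinaryMask,
    labels: BranchLabelVolume,
    truth_vessel: BinaryMask,
    truth_levels: BranchLabelVolume,
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
) -> MetricsReport:
    """Full metrics bundle for one pipeline run against phantom truth."""
    report = branch_level_agreement(labels, truth_levels, tolerance_mm)
    report.dice = dice_coefficient(vessel_mask, truth_vessel)
    pred_skel = labels.skeleton_mask()
    true_center = truth_levels.skeleton_mask()
    p, r = centerline_precision_recall(pred_skel, true_center, tolerance_mm)
    report.centerline_precision = p
    report.centerline_recall = r
    return report


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per (group, endpoint): n of non-missing values, mean, median."""
    if table.empty:
        raise ValidationError("animal table is empty")
    endpoints = [c for c in table.columns if c not in ("animal_id", "group")]
    rows = []
    for group, sub in table.groupby("group", sort=True):
        for col in endpoints:
            vals = sub[col].dropna()
            rows.append(
                {
                    "group": group,
                    "endpoint": col,
                    "n": int(len(vals)),
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "median": float(vals.median()) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows)
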