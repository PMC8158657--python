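"""Evaluation metrics: hard Dice score and 95th-percentile Hausdorff distance.

HD95 is the max of the two directed 95th-percentile distance distributions,
where each foreground voxel of one mask is assigned the Euclidean distance
(scaled by voxel spacing) to its nearest foreground voxel of the other mask.
Distances are computed over all foreground voxels (not extracted surfaces) via
a Euclidean distance transform; percentiles use linear interpolation between
order statistics, so results are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .volume_io import HierarchicalMasks

REGIONS = ("wt", "tc", "et")


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(np.unique(arr), [0, 1]).all():
        raise ValueError(f"{name} is not a binary mask")
    return arr.astype(bool)


def dice_score(s: np.ndarray, p: np.ndarray) -> float:
    """2|S∩P| / (|S|+|P|); both empty -> 1.0, exactly one empty -> 0.0."""
    s = _check_binary(s, "S")
    p = _check_binary(p, "P")
    if s.shape != p.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {p.shape}")
    ns, npx = int(s.sum()), int(p.sum())
    if ns == 0 and npx == 0:
        return 1.0
    if ns == 0 or npx == 0:
        return 0.0
    inter = int(np.logical_and(s, p).sum())
    return 2.0 * inter / (ns + npx)


def hausdorff95(s: np.ndarray, p: np.ndarray, spacing=(1.0, 1.0, 1.0),
                percentile: float = 95.0, method: str = "percentile") -> float:
    """95th-percentile (or ``scaled_max``: 0.95 x max) symmetric Hausdorff distance.

    Raises ValueError on an empty mask — callers use :func:`hd95_or_nan` for the
    flagged-undefined convention.
    """
    s = _check_binary(s, "S")
    p = _check_binary(p, "P")
    if s.shape != p.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {p.shape}")
    if not s.any() or not p.any():
        raise ValueError("hausdorff95 undefined for an empty mask")
    spacing = tuple(float(z) for z in spacing)
    # distance of every voxel to the nearest foreground voxel of each mask
    dt_p = ndimage.distance_transform_edt(~p, sampling=spacing)
    dt_s = ndimage.distance_transform_edt(~s, sampling=spacing)
    d_s_to_p = dt_p[s]
    d_p_to_s = dt_s[p]
    if method == "scaled_max":
        return 0.95 * max(float(d_s_to_p.max()), float(d_p_to_s.max()))
    if method != "percentile":
        raise ValueError(f"unknown method {method!r}")
    return max(float(np.percentile(d_s_to_p, percentile)),
               float(np.percentile(d_p_to_s, percentile)))


def hd95_or_nan(s, p, spacing=(1.0, 1.0, 1.0)) -> float:
    """HD95, or NaN (flagged-undefined) when either mask is empty."""
    s = np.asarray(s, bool)
    p = np.asarray(p, bool)
    if not s.any() or not p.any():
        return math.nan
    return hausdorff95(s, p, spacing)


@dataclasses.dataclass
class MetricReport:
    """Per-region Dice / HD95 for one subject (HD95 NaN when undefined)."""

    dice: dict
    hd95: dict
    subject_id: str = ""

    @property
    def region_average_dice(self) -> float:
        return float(np.mean([self.dice[r] for r in REGIONS]))

    def rows(self):
        for r in REGIONS:
            yield {"subject": self.subject_id, "region": r,
                   "dice": self.dice[r], "hd95": self.hd95[r]}


def evaluate_study(pred: HierarchicalMasks, gt: HierarchicalMasks,
                   spacing=(1.0, 1.0, 1.0), subject_id: str = "") -> MetricReport:
    if pred.wt.shape != gt.wt.shape:
        raise ValueError(f"shape mismatch: pred {pred.wt.shape} vs gt {gt.wt.shape}")
    dice, hd = {}, {}
    for r in REGIONS:
        pm, gm = getattr(pred, r), getattr(gt, r)
        dice[r] = dice_score(gm, pm)
        hd[r] = hd95_or_nan(gm, pm, spacing)
    return MetricReport(dice=dice, hd95=hd, subject_id=subject_id)


def aggregate_reports(reports: list[MetricReport]) -> dict:
    """Cohort means per region plus the region-average column (Table-style)."""
    out = {"dice": {}, "hd95": {}}
    for r in REGIONS:
        out["dice"][r] = float(np.mean([rep.dice[r] for rep in reports]))
        vals = [rep.hd95[r] for rep in reports if not math.isnan(rep.hd95[r])]
        out["hd95"][r] = float(np.mean(vals)) if vals else math.nan
    out["dice"]["average"] = float(np.mean([out["dice"][r] for r in REGIONS]))
    hd_vals = [out["hd95"][r] for r in REGIONS if not math.isnan(out["hd95"][r])]
    out["hd95"]["average"] = float(np.mean(hd_vals)) if hd_vals else math.nan
    return out


def reports_to_csv(reports: list[MetricReport]) -> str:
    lines = ["subject,region,dice,hd95"]
    for rep in reports:
        for row in rep.rows():
            hd = "nan" if math.isnan(row["hd95"]) else repr(row["hd95"])
            lines.append(f"{row['subject']},{row['region']},{row['dice']!r},{hd}")
    return "\n".join(lines) + "\n"
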