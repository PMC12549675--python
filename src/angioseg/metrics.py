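"""Segmentation evaluation: Dice, sensitivity, IoU and HD95.

Region overlap is computed from the pixel confusion counts

    DSC = 2·TP / (2·TP + FP + FN),   Sen = TP / (TP + FN),
    IoU = |A ∩ B| / |A ∪ B|,

with the empty-vs-empty convention DSC = IoU = Sen = 1.  Boundary agreement
uses the 95th-percentile Hausdorff distance: boundary pixels are the
8-connectivity erosion difference of each mask, directed nearest-neighbour
distances are computed both ways, and HD95 is the linearly interpolated
95th percentile of the *pooled* bidirectional distance multiset (the common
medical-segmentation reading; symmetric by construction).  Distances are in
pixels unless an isotropic ``spacing`` is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ConfusionCounts", "confusion_counts", "dsc", "sensitivity", "iou",
    "boundary_points", "hd95", "evaluate_pair", "aggregate",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _check_masks(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    for name, m in (("pred", pred), ("gt", gt)):
        u = np.unique(m)
        if not np.all(np.isin(u, (0, 1))):
            raise ValueError(f"{name} mask must be binary (0/1), got values {u[:5]}")
    return pred.astype(bool), gt.astype(bool)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary masks."""
    p, g = _check_masks(pred, gt)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dsc(counts: ConfusionCounts) -> float:
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 1.0 if denom == 0 else 2.0 * counts.tp / denom


def sensitivity(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return 1.0 if denom == 0 else counts.tp / denom


def iou(pred, gt) -> float:
    """Foreground intersection-over-union of two binary masks."""
    p, g = _check_masks(pred, gt)
    union = int(np.count_nonzero(p | g))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(p & g)) / union


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """(N, 2) coordinates of boundary pixels: mask minus its 8-connectivity
    erosion (frame border counts as background)."""
    m = np.asarray(mask).astype(bool)
    er = ndimage.binary_erosion(m, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(m & ~er)


def hd95(pred, gt, spacing: float = 1.0) -> float:
    """95th percentile of pooled bidirectional boundary distances.

    Raises ``ValueError`` when either mask is empty (the distance is
    undefined); aggregation treats that case as a missing value."""
    p, g = _check_masks(pred, gt)
    bp = boundary_points(p)
    bg = boundary_points(g)
    if len(bp) == 0 or len(bg) == 0:
        raise ValueError("hd95 undefined: a mask has no boundary")
    d_pg = cKDTree(bg).query(bp)[0]
    d_gp = cKDTree(bp).query(bg)[0]
    pooled = np.concatenate([d_pg, d_gp]) * spacing
    return float(np.percentile(pooled, 95))


def evaluate_pair(pred, gt, spacing: float = 1.0) -> dict:
    """All metrics for one prediction/ground-truth pair.

    ``hd95`` is ``nan`` when undefined (empty mask)."""
    counts = confusion_counts(pred, gt)
    out = {
        "dsc": dsc(counts),
        "sen": sensitivity(counts),
        "iou": iou(pred, gt),
    }
    try:
        out["hd95"] = hd95(pred, gt, spacing)
    except ValueError:
        warnings.warn("hd95 undefined for an empty mask; reported as nan")
        out["hd95"] = float("nan")
    return out


def aggregate(per_image: list[dict]) -> dict:
    """Unweighted mean over images; HD95 averages the defined values only."""
    if not per_image:
        raise ValueError("need at least one image")
    out = {}
    for key in ("dsc", "sen", "iou"):
        out["m" + key] = float(np.mean([m[key] for m in per_image]))
    hds = [m["hd95"] for m in per_image if np.isfinite(m.get("hd95", np.nan))]
    out["mhd95"] = float(np.mean(hds)) if hds else float("nan")
    return out
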