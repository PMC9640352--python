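"""Clinical segmentation evaluation: Dice, Jaccard, OS/US, HD95 and helpers.

All overlap metrics derive from the voxel confusion counts between a
ground-truth and a predicted binary mask:

    DSC = 2 TP / (2 TP + FP + FN)
    JAC = TP / (TP + FP + FN)
    OS  = 2 FP / (|GT| + |Pred|)        (spurious voxels)
    US  = 2 FN / (|GT| + |Pred|)        (missed voxels)

OS and US decompose the disagreement so that OS + US = 2(1 - DSC) — a useful
consistency check that holds exactly.  HD95 is the symmetric 95th-percentile
Hausdorff distance between the two mask surfaces, in mm, robust to a small
fraction of outlier boundary voxels.

Border stripping (morphological erosion by a voxel cube) removes the
boundary shell, where inter-rater and model disagreement concentrates, so
metrics can be re-read on the interior alone.  Mask combination (union /
intersection) supports comparing independently corrected segmentations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import UsageError
from .volume_io import BinaryMask, check_same_shape

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "dice",
    "jaccard",
    "over_seg",
    "under_seg",
    "hd95",
    "boundary_voxels",
    "border_strip",
    "combine_masks",
    "evaluate_pair",
    "summarize",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def gt_size(self) -> int:
        return self.tp + self.fn

    @property
    def pred_size(self) -> int:
        return self.tp + self.fp


@dataclass
class MetricReport:
    """Per-volume metric row; hd95 is None when either mask is empty."""

    dice: float
    jaccard: float
    os: float
    us: float
    hd95: float | None
    volume_id: str = ""


def _as_bool(m: BinaryMask | np.ndarray) -> np.ndarray:
    arr = m.data if isinstance(m, BinaryMask) else np.asarray(m)
    return arr.astype(bool)


def confusion_counts(gt: BinaryMask, pred: BinaryMask) -> ConfusionCounts:
    """Exact TP/FP/FN/TN voxel counts over the full grid."""
    g, p = _as_bool(gt), _as_bool(pred)
    check_same_shape(g, p)
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    tn = g.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dice(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN); both masks empty scores 1 by convention."""
    den = 2 * c.tp + c.fp + c.fn
    return 1.0 if den == 0 else 2.0 * c.tp / den


def jaccard(c: ConfusionCounts) -> float:
    den = c.tp + c.fp + c.fn
    return 1.0 if den == 0 else c.tp / den


def over_seg(c: ConfusionCounts) -> float:
    """2FP / (|GT| + |Pred|); ranges up to 2 when GT is empty."""
    den = c.gt_size + c.pred_size
    return 0.0 if den == 0 else 2.0 * c.fp / den


def under_seg(c: ConfusionCounts) -> float:
    """2FN / (|GT| + |Pred|); ranges up to 2 when Pred is empty."""
    den = c.gt_size + c.pred_size
    return 0.0 if den == 0 else 2.0 * c.fn / den


def boundary_voxels(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Index coordinates (n, 3) of foreground voxels with a face-adjacent
    background neighbor; the array border counts as background."""
    m = _as_bool(mask)
    structure = ndimage.generate_binary_structure(m.ndim, 1)
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    return np.argwhere(m & ~interior)


def hd95(gt: BinaryMask, pred: BinaryMask, spacing=None) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask surfaces, mm.

    Each directed distance set (boundary of A to nearest boundary voxel of B,
    Euclidean in physical coordinates) is reduced to its 95th percentile
    (linear interpolation between order statistics) before taking the max of
    the two directions.
    """
    g, p = _as_bool(gt), _as_bool(pred)
    check_same_shape(g, p)
    if not g.any() or not p.any():
        raise UsageError("hd95 requires both masks non-empty")
    if spacing is None:
        spacing = gt.spacing if isinstance(gt, BinaryMask) else (1.0, 1.0, 1.0)
    sp = np.asarray(spacing, dtype=np.float64)

    a = boundary_voxels(g) * sp
    b = boundary_voxels(p) * sp
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def border_strip(m: BinaryMask, cube_edge: int) -> BinaryMask:
    """Erode the mask by a cube_edge^3 structuring element (cube_edge odd).

    Removes a (cube_edge-1)/2-voxel shell from the mask surface so metrics
    can be evaluated on the interior region alone.
    """
    if cube_edge < 1 or cube_edge % 2 == 0:
        raise UsageError(f"cube_edge must be a positive odd integer, got {cube_edge}")
    if cube_edge == 1:
        return BinaryMask(m.data.copy(), m.spacing)
    structure = np.ones((cube_edge,) * 3, dtype=bool)
    eroded = ndimage.binary_erosion(_as_bool(m), structure=structure, border_value=0)
    return BinaryMask(eroded.astype(np.uint8), m.spacing)


def combine_masks(a: BinaryMask, b: BinaryMask, op: str) -> BinaryMask:
    """Element-wise union (logical or) or intersection (Hadamard product)."""
    check_same_shape(a.data, b.data)
    if op == "union":
        out = _as_bool(a) | _as_bool(b)
    elif op == "intersection":
        out = _as_bool(a) & _as_bool(b)
    else:
        raise UsageError(f"op must be 'union' or 'intersection', got {op!r}")
    return BinaryMask(out.astype(np.uint8), a.spacing)


def evaluate_pair(
    gt: BinaryMask, pred: BinaryMask, spacing=None, volume_id: str = ""
) -> MetricReport:
    """All five metrics for one ground-truth/prediction pair."""
    c = confusion_counts(gt, pred)
    g_empty = c.gt_size == 0
    p_empty = c.pred_size == 0
    hd = None if (g_empty or p_empty) else hd95(gt, pred, spacing)
    return MetricReport(
        dice=dice(c), jaccard=jaccard(c), os=over_seg(c), us=under_seg(c),
        hd95=hd, volume_id=volume_id,
    )


def summarize(reports: list[MetricReport]) -> pd.DataFrame:
    """Mean, sample SD (ddof=1), median and quartiles per metric.

    HD95 aggregates over the defined values only.  A single report has no
    sample variance; SD is reported as 0 with a warning.
    """
    if not reports:
        raise UsageError("summarize requires at least one report")
    frame = pd.DataFrame(
        {
            "dice": [r.dice for r in reports],
            "jaccard": [r.jaccard for r in reports],
            "os": [r.os for r in reports],
            "us": [r.us for r in reports],
            "hd95": [np.nan if r.hd95 is None else r.hd95 for r in reports],
        }
    )
    if len(reports) == 1:
        logger.warning("summarize: single report, SD undefined, reporting 0")
    out = pd.DataFrame(
        {
            "mean": frame.mean(),
            "sd": frame.std(ddof=1).fillna(0.0) if len(reports) > 1 else 0.0,
            "median": frame.median(),
            "q25": frame.quantile(0.25),
            "q75": frame.quantile(0.75),
            "n": frame.count(),
        }
    )
    return out
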