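"""Segmentation evaluation: Dice overlap, exact Hausdorff distance, accuracy.

All three criteria are computed per tissue class under one-vs-rest
binarisation, consistent with per-tissue reporting.  The Hausdorff distance
is the exact max-min form (no percentile variant) over voxel-center
coordinates scaled by the voxel spacing, so it is reported in millimetres
and is invariant to anisotropic grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff

from .volume_io import LabelVolume

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dice",
    "hausdorff",
    "accuracy",
    "evaluate_segmentation",
    "write_metric_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_shapes(gt: np.ndarray, seg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gt = np.asarray(gt, dtype=bool)
    seg = np.asarray(seg, dtype=bool)
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {seg.shape}")
    return gt, seg


def confusion_counts(gt: np.ndarray, seg: np.ndarray) -> ConfusionCounts:
    gt, seg = _check_shapes(gt, seg)
    tp = int(np.count_nonzero(gt & seg))
    fp = int(np.count_nonzero(~gt & seg))
    fn = int(np.count_nonzero(gt & ~seg))
    tn = int(np.count_nonzero(~gt & ~seg))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice(gt: np.ndarray, seg: np.ndarray) -> float:
    """Dice overlap 2TP / (2TP + FP + FN); 1.0 when both masks are empty."""
    c = confusion_counts(gt, seg)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def hausdorff(
    gt: np.ndarray,
    seg: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Exact symmetric Hausdorff distance between two binary masks, in mm.

    max( max_{p in G} min_{q in S} ||p-q||, max_{q in S} min_{p in G} ||q-p|| )
    over voxel centers scaled by ``spacing``.  Errors on an empty mask.
    """
    gt, seg = _check_shapes(gt, seg)
    if not gt.any() or not seg.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    sp = np.asarray(spacing, dtype=np.float64)
    p = np.argwhere(gt) * sp
    q = np.argwhere(seg) * sp
    return float(max(directed_hausdorff(p, q)[0], directed_hausdorff(q, p)[0]))


def accuracy(gt: np.ndarray, seg: np.ndarray) -> float:
    """Voxelwise agreement (TP + TN) / total."""
    c = confusion_counts(gt, seg)
    return (c.tp + c.tn) / c.total


def evaluate_segmentation(
    gt: LabelVolume,
    seg: LabelVolume,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    classes: dict[int, str] | None = None,
    evaluation_mask: np.ndarray | None = None,
    case: str = "case",
) -> pd.DataFrame:
    """Per-class metric table under one-vs-rest binarisation.

    Classes default to the non-background labels declared on the ground
    truth.  Metrics are computed inside ``evaluation_mask`` when given
    (typically the brain mask).  A class absent from both volumes is
    reported with Dice 1, NaN Hausdorff, and ``empty_class=True``.  The
    overall multiclass agreement is appended as class ``"overall"``.
    """
    if gt.shape != seg.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {seg.shape}")
    if classes is None:
        classes = {k: v for k, v in gt.label_names.items() if k != 0}
    g = gt.labels
    s = seg.labels
    if evaluation_mask is not None:
        em = np.asarray(evaluation_mask, dtype=bool)
        g = g[em]
        s = s[em]
        gt_grid = gt.labels.copy()
        seg_grid = seg.labels.copy()
        gt_grid[~em] = 0
        seg_grid[~em] = 0
    else:
        gt_grid, seg_grid = gt.labels, seg.labels

    rows = []
    for value, name in sorted(classes.items()):
        gmask, smask = g == value, s == value
        empty = not gmask.any() and not smask.any()
        if gmask.any() and smask.any():
            hd = hausdorff(gt_grid == value, seg_grid == value, spacing)
        else:
            hd = np.nan
        rows.append(
            {
                "case": case,
                "class": name,
                "dice": dice(gmask, smask),
                "hausdorff_mm": hd,
                "accuracy": accuracy(gmask, smask),
                "empty_class": empty,
            }
        )
    rows.append(
        {
            "case": case,
            "class": "overall",
            "dice": np.nan,
            "hausdorff_mm": np.nan,
            "accuracy": float(np.mean(g == s)) if g.size else np.nan,
            "empty_class": g.size == 0,
        }
    )
    return pd.DataFrame(rows)


def write_metric_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a metric table as CSV, with a JSON sidecar next to it."""
    path = Path(path)
    table.to_csv(path, index=False)
    table.to_json(path.with_suffix(".json"), orient="records", indent=2)
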