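"""Evaluation metrics: IoU against polygon ground truth, lateral and
angular error of the detected edge line, and per-sequence summaries.

* IoU is exact pixel counting between the predicted mask and the ground
  truth polygon rasterised with the same rasteriser the scene generator
  uses, so no rasterisation bias enters the comparison.
* Lateral error is the signed horizontal offset between the bottom-row
  intersections ("lowest points") of the estimated and true edge lines,
  divided by the image width — the fraction of the frame the guidance
  line is off by.
* Angular error is the absolute difference of the two lines'
  vertical-axis angles, wrapped into [0, 90] degrees.

Per-frame values keep their sign; summary rows report the mean +- sd of
IoU, |lateral| and angular magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .edges import detect_uncut_edge
from .errors import WscasError
from .geometry import EdgeLine, rasterize_polygon

__all__ = [
    "FrameMetrics",
    "intersection_over_union",
    "lateral_error",
    "angular_error",
    "evaluate_run",
    "summarize",
]

log = logging.getLogger(__name__)


@dataclass
class FrameMetrics:
    frame_id: int
    iou: float
    lateral_error: float  # signed ratio
    angular_error_deg: float


def intersection_over_union(pred_mask: np.ndarray, gt_polygon) -> float:
    """|pred & gt| / |pred | gt| by exact pixel counting.

    The polygon must be simple (non-self-intersecting); it is rasterised
    at the mask resolution.  The empty-vs-empty case is defined as 1.
    """
    mask = np.asarray(pred_mask).astype(bool)
    poly = np.asarray(gt_polygon, dtype=float)
    if not Polygon(poly).is_valid:
        raise ValueError("ground-truth polygon is self-intersecting or degenerate")
    gt = rasterize_polygon(poly, mask.shape)
    union = int((mask | gt).sum())
    if union == 0:
        return 1.0
    return int((mask & gt).sum()) / union


def lateral_error(pred: EdgeLine, gt: EdgeLine, image_width: int) -> float:
    """Signed (pred - gt) offset of the bottom-row intersections, as a
    fraction of the image width.  Negative when the estimate is left of
    the target."""
    return (pred.bottom_x - gt.bottom_x) / image_width


def angular_error(pred: EdgeLine, gt: EdgeLine) -> float:
    """Absolute difference of vertical-axis angles, wrapped to [0, 90]."""
    d = abs(pred.vertical_angle_deg - gt.vertical_angle_deg) % 180.0
    return min(d, 180.0 - d)


def evaluate_run(samples, segmenter, method: str = "wscas") -> pd.DataFrame:
    """Run a segmenter over a sequence and score every frame.

    ``segmenter`` maps an RGB image to a :class:`SegmentationMask` (or a
    ``(mask, extra)`` tuple, as the IPC baseline returns).  A frame on
    which segmentation or edge detection fails is recorded with NaN
    metrics and the failure reason; such frames are excluded from the
    summary, whose ``n`` column reports the count actually used.
    """
    if len(samples) == 0:
        raise ValueError("no samples to evaluate")
    rows = []
    for sample in samples:
        h, w = sample.mask.shape
        rec = {"frame_id": sample.frame_id, "method": method,
               "iou": np.nan, "lateral_error": np.nan,
               "angular_error_deg": np.nan, "failure": ""}
        try:
            seg = segmenter(sample.image)
            if isinstance(seg, tuple):
                seg = seg[0]
            rec["iou"] = intersection_over_union(seg.mask, sample.gt_crop_polygon)
            line = detect_uncut_edge(seg)
            rec["lateral_error"] = lateral_error(line, sample.gt_edge, w)
            rec["angular_error_deg"] = angular_error(line, sample.gt_edge)
        except WscasError as exc:
            rec["failure"] = f"{type(exc).__name__}: {exc}"
            log.warning("frame %s (%s): %s", sample.frame_id, method, exc)
        rows.append(rec)
    return pd.DataFrame(rows)


def summarize(frames: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd summary per method (|lateral| and angular magnitudes)."""
    out = []
    for method, grp in frames.groupby("method", sort=True):
        ok = grp.dropna(subset=["iou"])
        edge_ok = ok.dropna(subset=["lateral_error"])
        out.append(
            {
                "method": method,
                "n": len(edge_ok),
                "iou_mean": ok["iou"].mean(),
                "iou_sd": ok["iou"].std(ddof=1),
                "lateral_mean": edge_ok["lateral_error"].abs().mean(),
                "lateral_sd": edge_ok["lateral_error"].abs().std(ddof=1),
                "angular_mean_deg": edge_ok["angular_error_deg"].mean(),
                "angular_sd_deg": edge_ok["angular_error_deg"].std(ddof=1),
            }
        )
    return pd.DataFrame(out)
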