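"""Uncut-crop-edge extraction from the segmented mask.

The guidance reference is a single straight line: the right boundary of
the crop region, where it touches the harvested area.  The pipeline is

1. contour of the binary mask (exact inner morphological boundary; on a
   two-level image this is the Canny contour up to one pixel),
2. trim the top and bottom 10% of the contour's own row extent, then keep
   only the rightmost pixel of every remaining row — isolating the right
   side of the region,
3. rho-theta Hough voting over the filtered pixels, restricted to
   near-vertical normals, and averaging of every line above the vote
   threshold (mean rho, circular mean theta) into one representative line.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.morphology import erosion, footprint_rectangle
from skimage.transform import hough_line

from .cam import SegmentationMask
from .errors import DegenerateContourError, EmptyMaskError, NoLineError
from .geometry import EdgeLine

__all__ = [
    "extract_boundary_pixels",
    "trim_and_filter_rightmost",
    "fit_edge_line",
    "detect_uncut_edge",
]

#: the boundary is near-vertical by task geometry; Hough normals are kept
#: within +-45 degrees of the x axis (i.e. lines within 45 deg of vertical)
THETA_SPAN_DEG = 45
THETA_STEP_DEG = 1.0
#: cells within this fraction of the accumulator peak are averaged; the
#: peak itself must gather at least MIN_CONSENSUS of the pixels, otherwise
#: the pixel set has no line-like consensus at all
PEAK_FRACTION = 0.5
MIN_CONSENSUS = 0.10


def _as_bool_mask(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        mask = mask.mask
    return np.asarray(mask).astype(bool)


def extract_boundary_pixels(mask) -> np.ndarray:
    """Outer contour of the mask as an (n, 2) array of (x, y) pixels.

    Computed as the exact inner morphological boundary
    ``mask & ~erosion(mask)`` with a 3x3 footprint (pixels outside the
    canvas count as background, so a full-frame mask yields the image
    border).  Raises :class:`EmptyMaskError` on an empty mask.
    """
    m = _as_bool_mask(mask)
    if not m.any():
        raise EmptyMaskError("mask has no foreground pixels")
    # pad with background so pixels on the canvas border count as boundary
    interior = erosion(np.pad(m, 1), footprint_rectangle((3, 3)))[1:-1, 1:-1]
    boundary = m & ~interior
    ys, xs = np.nonzero(boundary)
    return np.column_stack([xs, ys])


def trim_and_filter_rightmost(
    boundary: np.ndarray, trim_fraction: float = 0.10
) -> np.ndarray:
    """Vertical trim + per-row rightmost-pixel filter.

    Rows within the top and bottom ``trim_fraction`` of the contour's own
    row extent are discarded; of the remaining rows, only the pixel with
    maximum x survives.  Raises :class:`DegenerateContourError` when the
    extent is too small to trim (fewer than 3 rows, or nothing left).
    """
    pts = np.asarray(boundary)
    if pts.size == 0:
        raise DegenerateContourError("empty boundary")
    xs, ys = pts[:, 0], pts[:, 1]
    y_min, y_max = int(ys.min()), int(ys.max())
    extent = y_max - y_min + 1
    if extent < 3:
        raise DegenerateContourError(f"contour spans only {extent} row(s)")
    n_trim = int(round(trim_fraction * extent))
    lo, hi = y_min + n_trim, y_max - n_trim
    keep = (ys >= lo) & (ys <= hi)
    if not keep.any():
        raise DegenerateContourError("trim removed every contour row")
    xs, ys = xs[keep], ys[keep]
    out = []
    for y in np.unique(ys):
        out.append((xs[ys == y].max(), y))
    return np.array(out)


def fit_edge_line(
    pixels: np.ndarray,
    height: int | None = None,
    vote_threshold: float | None = None,
) -> EdgeLine:
    """Average all Hough lines above the vote threshold into one line.

    A standard rho-theta accumulator (1 px x 1 deg bins, normals within
    +-45 deg of the x axis) votes over the pixel set.  With an explicit
    ``vote_threshold`` every cell reaching it contributes; by default the
    threshold adapts to half the accumulator peak — rho/theta quantisation
    spreads the votes of a slightly wobbly contour over neighbouring
    cells, so a fixed fraction of the pixel count would reject genuinely
    consensual lines — while the peak itself must still gather at least
    10% of the pixels.  The result has the mean rho and the circular mean
    theta (period 180 deg) of the contributing cells.  Raises
    :class:`NoLineError` when no cell qualifies.
    """
    pts = np.asarray(pixels)
    if pts.ndim != 2 or len(pts) < 2:
        raise NoLineError("need at least 2 pixels to vote for a line")
    if height is None:
        height = int(pts[:, 1].max()) + 1

    img = np.zeros((int(pts[:, 1].max()) + 1, int(pts[:, 0].max()) + 1), dtype=bool)
    img[pts[:, 1], pts[:, 0]] = True
    n_theta = int(round(2 * THETA_SPAN_DEG / THETA_STEP_DEG)) + 1
    thetas = np.deg2rad(np.linspace(-THETA_SPAN_DEG, THETA_SPAN_DEG, n_theta))
    acc, theta_out, rho_out = hough_line(img, theta=thetas)

    if vote_threshold is None:
        if acc.max() < MIN_CONSENSUS * len(pts):
            raise NoLineError(
                f"no line consensus: accumulator peak {acc.max()} below "
                f"{MIN_CONSENSUS:.0%} of {len(pts)} pixels"
            )
        vote_threshold = PEAK_FRACTION * acc.max()
    hit_r, hit_t = np.nonzero(acc >= vote_threshold)
    if len(hit_r) == 0:
        raise NoLineError(
            f"no Hough cell reached {vote_threshold:.1f} votes "
            f"(max {acc.max()} over {len(pts)} pixels)"
        )
    votes = acc[hit_r, hit_t].astype(float)
    rhos = rho_out[hit_r].astype(float)
    angs = theta_out[hit_t]  # already canonical within (-pi/4, pi/4)
    mean_rho = float(rhos.mean())
    # circular mean with period pi via angle doubling
    s = np.sin(2 * angs).mean()
    c = np.cos(2 * angs).mean()
    mean_theta = 0.5 * math.atan2(s, c)
    meta = {
        "n_lines_averaged": int(len(hit_r)),
        "n_filtered_pixels": int(len(pts)),
        "max_votes": int(acc.max()),
        "vote_threshold": float(vote_threshold),
        "votes": votes.tolist(),
    }
    return EdgeLine(rho=mean_rho, theta_deg=math.degrees(mean_theta), height=height,
                    meta=meta)


def detect_uncut_edge(mask, trim_fraction: float = 0.10) -> EdgeLine:
    """Full mask-to-line composition, in the mask's own frame coordinates.

    ``extract_boundary_pixels`` -> ``trim_and_filter_rightmost`` ->
    ``fit_edge_line``.  When the mask holds several retained components the
    fit uses all of their boundaries and the result is flagged in
    ``meta['multi_component']``.
    """
    boundary = extract_boundary_pixels(mask)
    filtered = trim_and_filter_rightmost(boundary, trim_fraction=trim_fraction)
    m = _as_bool_mask(mask)
    line = fit_edge_line(filtered, height=m.shape[0])
    if isinstance(mask, SegmentationMask) and mask.n_components > 1:
        line.meta["multi_component"] = True
    return line
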