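"""Line and polygon primitives shared by the scene generator, the edge
detector and the evaluation metrics.

Conventions (used everywhere in this package):

* ``x`` is the column index, ``y`` the row index, origin at the top-left,
  0-based.  A pixel ``(x, y)`` has its centre at the point ``(x, y)``; it
  covers the square ``[x-0.5, x+0.5) x [y-0.5, y+0.5)``.
* A straight line is stored in normal (rho-theta) form:
  ``x*cos(theta) + y*sin(theta) = rho`` with ``theta`` in degrees in
  ``[0, 180)`` and ``rho`` signed.  A vertical line at column ``c`` is
  ``(rho=c, theta=0)``.
* The *vertical-axis angle* of a near-vertical line is the signed angle
  between the line and the image vertical, positive when the top of the
  line leans towards larger ``x`` (to the right on screen).  For
  ``theta`` in ``[0, 90]`` it equals ``theta``; for ``theta`` in
  ``(90, 180)`` it equals ``theta - 180``.
* The "lowest point" of a line is its intersection with the bottom pixel
  row ``y = height - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EdgeLine", "rasterize_polygon"]


@dataclass(frozen=True)
class EdgeLine:
    """A single straight line in image coordinates, rho-theta form.

    Parameters
    ----------
    rho:
        Signed distance (pixels) from the origin to the line along its
        normal.
    theta_deg:
        Normal angle, degrees, canonicalised into ``[0, 180)``.
    height:
        Height of the image the line lives in; needed to derive the
        bottom-row intersection.
    meta:
        Optional free-form detector metadata (vote counts, flags).
    """

    rho: float
    theta_deg: float
    height: int
    meta: dict = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        rho, theta = float(self.rho), float(self.theta_deg)
        theta_c = theta % 180.0
        # theta wrapped by 180 flips the normal direction, so rho flips sign
        if abs((theta - theta_c) / 180.0) % 2 == 1:
            rho = -rho
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "theta_deg", theta_c)

    @classmethod
    def from_vertical_angle(
        cls, bottom_x: float, angle_deg: float, height: int, meta: dict | None = None
    ) -> "EdgeLine":
        """Line through ``(bottom_x, height-1)`` leaning ``angle_deg`` off
        the vertical (positive = top leans right)."""
        a = math.radians(angle_deg)
        rho = bottom_x * math.cos(a) + (height - 1) * math.sin(a)
        return cls(rho=rho, theta_deg=angle_deg, height=height, meta=meta)

    @property
    def vertical_angle_deg(self) -> float:
        """Signed angle from the image vertical axis in ``(-90, 90]``."""
        t = self.theta_deg
        return t if t <= 90.0 else t - 180.0

    @property
    def bottom_x(self) -> float:
        """x-coordinate of the intersection with row ``y = height - 1``."""
        t = math.radians(self.theta_deg)
        c = math.cos(t)
        if abs(c) < 1e-9:
            raise ValueError("horizontal line has no bottom-row intersection")
        return (self.rho - (self.height - 1) * math.sin(t)) / c

    def x_at_row(self, y: float) -> float:
        t = math.radians(self.theta_deg)
        c = math.cos(t)
        if abs(c) < 1e-9:
            raise ValueError("horizontal line has no unique x at a row")
        return (self.rho - y * math.sin(t)) / c

    def distance_to(self, x: float, y: float) -> float:
        """Unsigned point-to-line distance in pixels."""
        t = math.radians(self.theta_deg)
        return abs(x * math.cos(t) + y * math.sin(t) - self.rho)

    def to_dict(self) -> dict:
        return {
            "rho": float(self.rho),
            "theta_deg": float(self.theta_deg),
            "bottom_x": float(self.bottom_x),
            "height": int(self.height),
        }


def rasterize_polygon(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple polygon onto a pixel grid (even-odd rule, pixel
    centres).

    A pixel is set when its centre lies inside the polygon; centres exactly
    on a right/bottom boundary are outside, centres on a left/top boundary
    are inside (half-open rule), so abutting polygons tile without overlap.
    The scene generator and the IoU metric share this rasterizer, which
    removes any rasterisation bias between ground truth and evaluation.

    Parameters
    ----------
    vertices:
        Sequence of ``(x, y)`` vertex coordinates (floats), in order;
        closing edge is implicit.
    shape:
        ``(height, width)`` of the output grid.

    Returns
    -------
    Boolean array of the given shape.
    """
    h, w = shape
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    out = np.zeros((h, w), dtype=bool)
    x0, y0 = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    keep = y0 != y1  # horizontal edges never cross a scanline
    x0, y0, x1, y1 = x0[keep], y0[keep], x1[keep], y1[keep]
    if len(x0) == 0:
        return out
    for yc in range(h):
        crosses = (y0 <= yc) != (y1 <= yc)
        if not crosses.any():
            continue
        xi = x0[crosses] + (yc - y0[crosses]) * (x1[crosses] - x0[crosses]) / (
            y1[crosses] - y0[crosses]
        )
        xi.sort()
        # interval [a, b): centre on the left crossing is inside, on the
        # right crossing outside
        for a, b in xi.reshape(-1, 2):
            lo = max(0, math.ceil(a))
            hi = min(w, math.ceil(b))
            if hi > lo:
                out[yc, lo:hi] = True
    return out
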