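"""Synthetic combine-harvester front-view scenes.

Real guidance footage shows three areas from the operator's viewpoint: the
standing (uncut) crop on the left, the already-harvested stubble on the
right, and a background band (sky / far field) above the horizon.  The
boundary between crop and stubble — the uncut crop edge — is near-vertical
and drifts sideways as the harvester advances.  This module renders that
structure with pixel-perfect class masks and an analytic ground-truth edge
line, so every downstream stage (patch dataset, classifier, CAM
segmentation, edge detection, metrics) can be tested without field data.

Classes are encoded as ``0 = background``, ``1 = uncut crop``,
``2 = harvested``.  The three textures are deliberately separable by local
colour/texture — the only cue available to a patch-level classifier:

* crop: green-yellow base with dense 1-2 px vertical stalk strokes,
* harvested: brown base with horizontal stubble stripes and speckle,
* background: pale sky gradient.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .errors import GeometryError
from .geometry import EdgeLine

__all__ = [
    "TextureParams",
    "SceneSpec",
    "SceneSample",
    "generate_scene",
    "generate_sequence",
    "sample_frame_indices",
    "BACKGROUND",
    "CROP",
    "HARVESTED",
]

BACKGROUND, CROP, HARVESTED = 0, 1, 2


@dataclass(frozen=True)
class TextureParams:
    """Per-class rendering parameters (8-bit RGB scale).

    ``stroke_density`` is the expected number of crop stalk strokes per
    1000 canvas pixels; stripe/speckle parameters shape the stubble.
    """

    crop_color: tuple = (92, 148, 58)
    crop_jitter: float = 22.0
    stroke_density: float = 4.0
    stroke_shade: float = 45.0
    harvested_color: tuple = (156, 118, 72)
    stripe_amp: float = 16.0
    stripe_period: int = 7
    speckle_frac: float = 0.04
    background_top: tuple = (168, 192, 222)
    background_bottom: tuple = (214, 216, 224)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry + appearance of one synthetic frame.

    ``edge_angle_deg`` is the signed angle of the crop/harvested boundary
    measured from the image vertical (positive = top of the edge leans
    right); it is kept within +-30 degrees, matching the near-vertical
    task geometry.  ``edge_bottom_x`` is the column where the boundary
    meets the bottom pixel row.
    """

    width: int = 360
    height: int = 360
    horizon_row: int = 120
    edge_bottom_x: float = 200.0
    edge_angle_deg: float = 5.0
    texture_params: TextureParams = field(default_factory=TextureParams)
    noise_sigma: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.horizon_row < self.height):
            raise ValueError(f"horizon_row {self.horizon_row} outside [0, {self.height})")
        if not (0 <= self.edge_bottom_x < self.width):
            raise ValueError(f"edge_bottom_x {self.edge_bottom_x} outside [0, {self.width})")
        if abs(self.edge_angle_deg) > 30:
            raise ValueError("edge_angle_deg must be within +-30 degrees (near-vertical boundary)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["texture_params"] = asdict(self.texture_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        d = dict(d)
        tp = d.pop("texture_params", None)
        if tp is not None:
            tp = TextureParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in tp.items()})
            d["texture_params"] = tp
        return cls(**d)


@dataclass
class SceneSample:
    """One rendered frame with full ground truth."""

    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray  # H x W, uint8, values {0, 1, 2}
    gt_edge: EdgeLine
    gt_crop_polygon: np.ndarray  # (n, 2) float (x, y) vertices
    spec: SceneSpec
    frame_id: int = 0


def _boundary_columns(spec: SceneSpec) -> np.ndarray:
    """Continuous boundary x(y) for every field-band row (crop iff x < x(y))."""
    ys = np.arange(spec.horizon_row, spec.height)
    t = math.tan(math.radians(spec.edge_angle_deg))
    return spec.edge_bottom_x + (spec.height - 1 - ys) * t


def _crop_polygon(spec: SceneSpec) -> np.ndarray:
    """Vertices of the crop region in pixel-centre coordinates.

    The region is bounded left by ``x = -0.5``, top/bottom by the field
    band, and right by the ground-truth line clipped to the canvas; it
    rasterizes (even-odd rule, pixel centres) exactly to ``mask == 1``.
    """
    h, w = spec.height, spec.width
    y_t, y_b = spec.horizon_row - 0.5, h - 0.5
    t = math.tan(math.radians(spec.edge_angle_deg))

    def f(y):
        return spec.edge_bottom_x + (h - 1 - y) * t

    def clamp(x):
        return min(max(x, -0.5), w - 0.5)

    right = [(clamp(f(y_t)), y_t)]
    # the boundary is monotone in y; insert the vertex where it crosses a
    # canvas side, if that happens inside the band
    if t != 0.0:
        for xlim in (-0.5, w - 0.5):
            y_star = (h - 1) - (xlim - spec.edge_bottom_x) / t
            if y_t < y_star < y_b and min(f(y_t), f(y_b)) < xlim < max(f(y_t), f(y_b)):
                right.append((xlim, y_star))
    right.sort(key=lambda v: v[1])  # walk down the right side
    right.append((clamp(f(y_b)), y_b))
    verts = [(-0.5, y_t)] + right + [(-0.5, y_b)]
    return np.array(verts, dtype=float)


def _render_textures(spec: SceneSpec, rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    h, w = spec.height, spec.width
    tp = spec.texture_params

    # crop: per-column hue jitter + short dark vertical stalk strokes
    crop = np.empty((h, w, 3), dtype=np.float64)
    base = np.asarray(tp.crop_color, dtype=float)
    col_jit = rng.uniform(-1, 1, size=(w, 3)) * tp.crop_jitter * np.array([0.6, 1.0, 0.6])
    crop[:] = base[None, None, :] + col_jit[None, :, :]
    n_strokes = int(tp.stroke_density * h * w / 1000.0)
    if n_strokes:
        sx = rng.integers(0, w, size=n_strokes)
        sy = rng.integers(0, h, size=n_strokes)
        slen = rng.integers(8, 30, size=n_strokes)
        swid = rng.integers(1, 3, size=n_strokes)
        shade = rng.uniform(-tp.stroke_shade, tp.stroke_shade * 0.3, size=n_strokes)
        for x0, y0, L, ww_, s in zip(sx, sy, slen, swid, shade):
            crop[y0 : min(y0 + L, h), x0 : min(x0 + ww_, w)] += s

    # harvested: horizontal stubble stripes + per-row jitter + bright speckle
    harv = np.empty((h, w, 3), dtype=np.float64)
    hbase = np.asarray(tp.harvested_color, dtype=float)
    rows = np.arange(h)
    stripe = tp.stripe_amp * np.sin(2 * math.pi * rows / max(tp.stripe_period, 2))
    row_jit = rng.uniform(-0.5, 0.5, size=(h,)) * tp.stripe_amp
    harv[:] = hbase[None, None, :] + (stripe + row_jit)[:, None, None]
    n_speck = int(tp.speckle_frac * h * w)
    if n_speck:
        py = rng.integers(0, h, size=n_speck)
        px = rng.integers(0, w, size=n_speck)
        harv[py, px] += rng.uniform(10, 60, size=(n_speck, 1))

    # background: vertical luminance gradient
    top = np.asarray(tp.background_top, dtype=float)
    bot = np.asarray(tp.background_bottom, dtype=float)
    frac = (rows / max(h - 1, 1))[:, None, None]
    bg = top[None, None, :] * (1 - frac) + bot[None, None, :] * frac
    bg = np.broadcast_to(bg, (h, w, 3)).copy()
    bg += rng.normal(0, 2.0, size=(h, w, 1))
    return bg, crop, harv


def generate_scene(spec: SceneSpec) -> SceneSample:
    """Render one frame.

    Deterministic: identical ``spec`` (including ``seed``) gives
    bit-identical output.  Raises :class:`GeometryError` when the boundary
    leaves one of the two field classes empty (edge entirely outside the
    field band).
    """
    spec.validate()
    h, w = spec.height, spec.width

    mask = np.zeros((h, w), dtype=np.uint8)
    xcols = _boundary_columns(spec)
    cols = np.arange(w)
    band = cols[None, :] < xcols[:, None]
    mask[spec.horizon_row :] = np.where(band, CROP, HARVESTED)

    n_crop = int((mask == CROP).sum())
    n_harv = int((mask == HARVESTED).sum())
    if n_crop == 0 or n_harv == 0:
        missing = "crop" if n_crop == 0 else "harvested"
        raise GeometryError(
            f"edge at bottom_x={spec.edge_bottom_x}, angle={spec.edge_angle_deg} deg "
            f"leaves the {missing} region empty"
        )

    rng = np.random.default_rng(spec.seed)
    bg, crop_tex, harv_tex = _render_textures(spec, rng)
    img = np.where((mask == CROP)[..., None], crop_tex, harv_tex)
    img = np.where((mask == BACKGROUND)[..., None], bg, img)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    gt_edge = EdgeLine.from_vertical_angle(spec.edge_bottom_x, spec.edge_angle_deg, h)
    poly = _crop_polygon(spec)
    return SceneSample(image=img, mask=mask, gt_edge=gt_edge, gt_crop_polygon=poly, spec=spec)


def generate_sequence(
    n_frames: int,
    start_spec: SceneSpec,
    drift_bottom_x: float = 0.0,
    drift_angle_deg: float = 0.0,
) -> list[SceneSample]:
    """Render a harvesting pass: frame ``i`` applies ``i`` times the
    per-frame drift to the edge position/angle and uses ``seed + i``.

    When the cumulative drift pushes the edge off-image (or leaves a field
    class empty) before ``n_frames``, the sequence is truncated and a
    warning is emitted recording the first invalid frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    samples: list[SceneSample] = []
    for i in range(n_frames):
        spec_i = replace(
            start_spec,
            edge_bottom_x=start_spec.edge_bottom_x + i * drift_bottom_x,
            edge_angle_deg=start_spec.edge_angle_deg + i * drift_angle_deg,
            seed=start_spec.seed + i,
        )
        try:
            sample = generate_scene(spec_i)
        except (GeometryError, ValueError) as exc:
            warnings.warn(
                f"sequence truncated at frame {i}/{n_frames}: {exc}",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        sample.frame_id = i
        samples.append(sample)
    return samples


def sample_frame_indices(n_total: int, step: int = 15) -> np.ndarray:
    """Indices of frames kept when subsampling a raw stream every ``step``
    frames (e.g. a 30 fps recording sampled at 2 Hz)."""
    if n_total < 1 or step < 1:
        raise ValueError("n_total and step must be positive")
    return np.arange(0, n_total, step)
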