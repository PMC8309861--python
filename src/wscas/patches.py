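"""Class-specific patch extraction and the image-level-labelled dataset.

The only supervision the method uses is one class label per patch.  Each
frame contributes one patch per class: the largest axis-aligned window
lying (almost) entirely inside that class's region.  Patches are later fed
to the classifier through random square crops, so every window must admit
at least one ``crop_size`` x ``crop_size`` crop.

The pure-region search is exact: the largest all-pure rectangle inside the
class mask is found with the classic row-histogram stack algorithm (every
maximal rectangle is enumerated, numba-compiled).  For the crop class,
whose real-world boundary is ragged and hard to annotate at pixel level,
the purity threshold is relaxed below 1 and the pure rectangle is then
grown greedily side by side while the window purity stays above the
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .errors import NoRegionError
from .scenes import SceneSample

__all__ = [
    "LabeledPatch",
    "PatchSplit",
    "DEFAULT_PURITY",
    "crop_class_region",
    "build_patch_dataset",
    "random_crop_view",
    "manifest_dataframe",
]

log = logging.getLogger(__name__)

#: interior classes must be perfectly pure; the crop class tolerates a
#: ragged boundary (pixel-accurate annotation at the crop border is the
#: hard part in real imagery)
DEFAULT_PURITY = {0: 1.0, 1: 0.95, 2: 1.0}


@dataclass
class LabeledPatch:
    """A class-pure sub-image with an image-level label."""

    pixels: np.ndarray  # h x w x 3 uint8
    label: int
    source_frame: int
    purity: float
    x0: int = 0
    y0: int = 0

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PatchSplit:
    """Half/half train-validation split of the patch set."""

    train: list = field(default_factory=list)
    val: list = field(default_factory=list)
    skipped: list = field(default_factory=list)  # (frame_id, reason)

    def class_counts(self) -> dict:
        counts: dict[int, int] = {}
        for p in self.train + self.val:
            counts[p.label] = counts.get(p.label, 0) + 1
        return counts


@njit(cache=True)
def _largest_pure_rect(ok, min_size):  # pragma: no cover - numba
    """Largest-area all-true rectangle with both sides >= min_size.

    Returns (area, y0, x0, h, w); area 0 when none exists.  Ties in area
    resolve to the topmost, then leftmost maximal rectangle.
    """
    n_rows, n_cols = ok.shape
    heights = np.zeros(n_cols, dtype=np.int64)
    stack_pos = np.empty(n_cols + 1, dtype=np.int64)
    stack_h = np.empty(n_cols + 1, dtype=np.int64)
    best_area, best_y, best_x, best_h, best_w = 0, 0, 0, 0, 0
    for r in range(n_rows):
        for c in range(n_cols):
            heights[c] = heights[c] + 1 if ok[r, c] else 0
        top = -1
        for c in range(n_cols + 1):
            cur = heights[c] if c < n_cols else 0
            start = c
            while top >= 0 and stack_h[top] >= cur:
                hh = stack_h[top]
                ss = stack_pos[top]
                top -= 1
                ww = c - ss
                if hh >= min_size and ww >= min_size:
                    area = hh * ww
                    y0 = r - hh + 1
                    if area > best_area or (
                        area == best_area
                        and (y0 < best_y or (y0 == best_y and ss < best_x))
                    ):
                        best_area, best_y, best_x, best_h, best_w = area, y0, ss, hh, ww
                start = ss
            if top < 0 or stack_h[top] < cur:
                top += 1
                stack_pos[top] = start
                stack_h[top] = cur
    return best_area, best_y, best_x, best_h, best_w


def _window_purity(integral: np.ndarray, y0: int, x0: int, h: int, w: int) -> float:
    inside = (
        integral[y0 + h, x0 + w]
        - integral[y0, x0 + w]
        - integral[y0 + h, x0]
        + integral[y0, x0]
    )
    return inside / (h * w)


def _grow_while_pure(integral, y0, x0, h, w, shape, threshold):
    """Greedy one-step-per-side expansion while purity >= threshold."""
    img_h, img_w = shape
    grew = True
    while grew:
        grew = False
        # fixed direction order keeps the result deterministic
        if y0 > 0 and _window_purity(integral, y0 - 1, x0, h + 1, w) >= threshold:
            y0, h, grew = y0 - 1, h + 1, True
        if x0 > 0 and _window_purity(integral, y0, x0 - 1, h, w + 1) >= threshold:
            x0, w, grew = x0 - 1, w + 1, True
        if y0 + h < img_h and _window_purity(integral, y0, x0, h + 1, w) >= threshold:
            h, grew = h + 1, True
        if x0 + w < img_w and _window_purity(integral, y0, x0, h, w + 1) >= threshold:
            w, grew = w + 1, True
    return y0, x0, h, w


def crop_class_region(
    sample: SceneSample,
    class_id: int,
    crop_size: int = 360,
    purity_threshold: float | None = None,
) -> LabeledPatch:
    """Extract the class-specific patch for one class of one frame.

    The window is the largest all-pure rectangle admitting a
    ``crop_size`` square crop (exact search); when the purity threshold is
    below 1 the window is then grown greedily while its purity holds.
    Raises :class:`NoRegionError` when no admissible window exists.
    """
    if purity_threshold is None:
        purity_threshold = DEFAULT_PURITY.get(class_id, 1.0)
    ok = np.ascontiguousarray(sample.mask == class_id)
    area, y0, x0, h, w = _largest_pure_rect(ok, min_size=crop_size)
    if area == 0:
        raise NoRegionError(
            class_id,
            f"frame {sample.frame_id}: no pure {crop_size}x{crop_size} window for "
            f"class {class_id}",
        )
    if purity_threshold < 1.0:
        integral = np.zeros((ok.shape[0] + 1, ok.shape[1] + 1), dtype=np.int64)
        np.cumsum(np.cumsum(ok, axis=0), axis=1, out=integral[1:, 1:])
        y0, x0, h, w = _grow_while_pure(
            integral, y0, x0, h, w, ok.shape, purity_threshold
        )
        purity = _window_purity(integral, y0, x0, h, w)
    else:
        purity = 1.0
    return LabeledPatch(
        pixels=sample.image[y0 : y0 + h, x0 : x0 + w].copy(),
        label=class_id,
        source_frame=sample.frame_id,
        purity=float(purity),
        x0=int(x0),
        y0=int(y0),
    )


def build_patch_dataset(
    samples: list[SceneSample],
    crop_size: int = 360,
    purity: dict | None = None,
) -> PatchSplit:
    """One patch per class per frame; half/half train-validation split.

    Frames that fail to yield all three patches are skipped and logged.
    Successful frames alternate between the train and validation halves
    (even position -> train), so per-class counts differ by at most one
    between the halves and the construction is reproducible.
    """
    purity = purity or DEFAULT_PURITY
    split = PatchSplit()
    kept = 0
    for sample in samples:
        try:
            trio = [
                crop_class_region(sample, c, crop_size, purity.get(c))
                for c in (0, 1, 2)
            ]
        except NoRegionError as exc:
            log.warning("skipping frame %s: %s", sample.frame_id, exc)
            split.skipped.append((sample.frame_id, str(exc)))
            continue
        side = split.train if kept % 2 == 0 else split.val
        side.extend(trio)
        kept += 1
    log.info(
        "patch dataset: %d frames kept, %d skipped, %d patches (%s)",
        kept,
        len(split.skipped),
        len(split.train) + len(split.val),
        split.class_counts(),
    )
    return split


def random_crop_view(
    patch: LabeledPatch,
    crop_size: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """A uniformly random ``crop_size`` square crop of the patch.

    The origin is uniform over all admissible positions; pass either a
    ``seed`` or an existing ``rng`` for determinism.
    """
    h, w = patch.height, patch.width
    if h < crop_size or w < crop_size:
        raise ValueError(
            f"patch {h}x{w} smaller than crop size {crop_size} (precondition violated)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    y0 = int(rng.integers(0, h - crop_size + 1))
    x0 = int(rng.integers(0, w - crop_size + 1))
    return patch.pixels[y0 : y0 + crop_size, x0 : x0 + crop_size]


def manifest_dataframe(split: PatchSplit):
    """Patch manifest (one row per patch) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for name, part in (("train", split.train), ("val", split.val)):
        for i, p in enumerate(part):
            rows.append(
                {
                    "patch_id": f"{name}-{i:04d}",
                    "source_frame": p.source_frame,
                    "label": p.label,
                    "x0": p.x0,
                    "y0": p.y0,
                    "w": p.width,
                    "h": p.height,
                    "purity": p.purity,
                    "split": name,
                }
            )
    return pd.DataFrame(rows)
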