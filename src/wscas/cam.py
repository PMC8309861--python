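"""From classifier to segmenter: class activation maps and the crop mask.

A class activation map (CAM) re-uses the trained GAP-head weights
spatially: with final conv features f_k(x, y) and head weights omega_k^c,

    M_c(x, y) = sum_k omega_k^c * f_k(x, y).

Because GAP and the weighted sum commute, the spatial mean of M_c is
exactly the class logit — the CAM redistributes the classifier's evidence
over space.  A categorical softmax across classes at every pixel turns the
three CAMs into per-pixel class probabilities, which are bilinearly
upsampled to the input resolution (softmax first, then upsampling:
interpolation is linear, so the per-pixel probability sum stays 1).  The
crop mask is the per-pixel argmax, cleaned by 8-connected component
filtering to drop small spurious regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize

from .classifier import ConvGapNet
from .errors import ModelError
from .nn import softmax
from .scenes import CROP, BACKGROUND

__all__ = [
    "SegmentationMask",
    "compute_cams",
    "pixel_class_probabilities",
    "segment_crop_area",
    "filter_small_components",
]


@dataclass
class SegmentationMask:
    """Binary crop mask plus the connected components kept by filtering."""

    mask: np.ndarray  # H x W bool
    components: list = field(default_factory=list)  # (area, (min_r, min_c, max_r, max_c))

    @property
    def n_components(self) -> int:
        return len(self.components)


def compute_cams(maps: np.ndarray, head: np.ndarray) -> np.ndarray:
    """Class activation maps, one per class.

    maps: (K, h, w) final conv activations; head: (C, K) GAP-to-class
    weights.  Returns (C, h, w) with M_c = sum_k omega_k^c f_k exactly.
    """
    maps = np.asarray(maps)
    head = np.asarray(head)
    if maps.ndim != 3 or head.ndim != 2 or head.shape[1] != maps.shape[0]:
        raise ValueError(
            f"shape mismatch: head {head.shape} vs {maps.shape[0]} feature maps"
        )
    return np.tensordot(head, maps, axes=([1], [0]))


def pixel_class_probabilities(
    cams: np.ndarray,
    out_shape: tuple[int, int] | None = None,
    upsample_first: bool = False,
) -> np.ndarray:
    """Per-pixel categorical softmax across classes, then bilinear
    upsampling to ``out_shape``.

    With ``upsample_first`` the CAMs are upsampled before the softmax (the
    two orders differ slightly; softmax-first preserves the per-pixel
    normalisation under interpolation and is the default).  Returns
    (C, H, W) with channel sums 1 at every pixel.
    """
    cams = np.asarray(cams, dtype=np.float64)
    if cams.ndim != 3 or cams.shape[0] < 2:
        raise ValueError("need (C, h, w) CAMs with at least 2 classes")

    def _softmax_cw(a):
        return np.moveaxis(softmax(np.moveaxis(a, 0, -1)), -1, 0)

    def _up(a, shape):
        return np.stack(
            [
                resize(ch, shape, order=1, mode="edge", anti_aliasing=False,
                       preserve_range=True)
                for ch in a
            ]
        )

    if out_shape is None or tuple(out_shape) == cams.shape[1:]:
        return _softmax_cw(cams)
    if upsample_first:
        return _softmax_cw(_up(cams, out_shape))
    return _up(_softmax_cw(cams), out_shape)


def filter_small_components(mask: np.ndarray, min_area: int) -> SegmentationMask:
    """Drop 8-connected components smaller than ``min_area`` pixels."""
    mask = np.asarray(mask).astype(bool)
    labels = cc_label(mask, connectivity=2)
    out = np.zeros_like(mask)
    comps = []
    for region in regionprops(labels):
        if region.area >= min_area:
            out[labels == region.label] = True
            comps.append((int(region.area), tuple(int(v) for v in region.bbox)))
    return SegmentationMask(mask=out, components=comps)


def _working_size(h: int, w: int, max_side: int) -> tuple[int, int]:
    """Largest multiple-of-8 size fitting the frame, capped at ``max_side``."""
    wh = min((h // 8) * 8, max_side)
    ww = min((w // 8) * 8, max_side)
    if wh == 0 or ww == 0:
        raise ModelError(f"frame {h}x{w} too small for the stride-8 backbone")
    return wh, ww


def segment_crop_area(
    image: np.ndarray,
    model: ConvGapNet,
    min_area: int | None = None,
    crop_class: int = CROP,
    max_side: int | None = None,
) -> SegmentationMask:
    """Segment the uncut crop area of a full frame.

    The network is fully convolutional, so inference runs at the native
    frame resolution rounded down to a multiple of 8 (bilinear resize),
    capped at ``max_side`` (defaults to the model's training input size or
    360, whichever is larger).  A pixel belongs to the crop iff the crop
    class wins the per-pixel argmax of the upsampled probabilities, ties
    resolving to background; the mask is then component-filtered and
    registered back to the original frame size by nearest-neighbour
    scaling.  ``min_area`` defaults to 0.5% of the frame pixels.
    """
    if model.history is None:
        raise ModelError(
            "model has no training history; train it (or mark hand-set "
            "oracle weights) before segmenting"
        )
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB image")
    h, w = img.shape[:2]
    if max_side is None:
        max_side = max(model.config.input_size, 360)
    wh, ww = _working_size(h, w, max_side)
    if (wh, ww) != (h, w):
        work = resize(img.astype(np.float64), (wh, ww), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
        work = np.clip(work, 0, 255).astype(np.uint8)
    else:
        work = img

    maps = model.feature_maps(work)
    cams = compute_cams(maps, model.head_weights)
    probs = pixel_class_probabilities(cams, out_shape=(wh, ww))
    # argmax with ties toward background: background is class 0 and
    # np.argmax returns the first maximum
    order = [BACKGROUND] + [c for c in range(probs.shape[0]) if c != BACKGROUND]
    labels_work = np.array(order)[np.argmax(probs[order], axis=0)]
    crop_mask = labels_work == crop_class

    if min_area is None:
        min_area = int(round(0.005 * h * w))
    seg = filter_small_components(crop_mask, min_area=min_area)
    if (wh, ww) != (h, w):
        ys = (np.arange(h) * wh / h).astype(int)
        xs = (np.arange(w) * ww / w).astype(int)
        full = seg.mask[np.ix_(ys, xs)]
        seg = SegmentationMask(mask=full, components=seg.components)
    return seg
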