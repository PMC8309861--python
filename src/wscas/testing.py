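"""Hand-constructed reference models for tests and examples.

The colour-oracle model is a :class:`~wscas.classifier.ConvGapNet` whose
weights are set by hand instead of trained: the first block copies the
signed RGB values into paired +/- channels (ReLU splits sign), the middle
blocks pass them through, and the last block computes a nearest-centroid
linear discriminant against the three synthetic texture colours.  Its
class activation maps therefore score each pixel by colour proximity,
which segments noiseless synthetic scenes near-perfectly — an
implementation-independent reference point for the CAM machinery and for
baseline comparisons.
"""

from __future__ import annotations

import numpy as np

from .classifier import BackboneConfig, ConvGapNet, N_CLASSES
from .scenes import TextureParams

__all__ = ["default_class_colors", "make_color_oracle_model"]


def default_class_colors(tp: TextureParams | None = None) -> np.ndarray:
    """Mean rendered RGB per class (background, crop, harvested)."""
    tp = tp or TextureParams()
    bg = (np.asarray(tp.background_top, float) + np.asarray(tp.background_bottom)) / 2
    return np.stack([bg, np.asarray(tp.crop_color, float),
                     np.asarray(tp.harvested_color, float)])


def make_color_oracle_model(
    class_colors: np.ndarray | None = None,
    config: BackboneConfig | None = None,
) -> ConvGapNet:
    """Build the nearest-colour-centroid oracle.

    The discriminant for class c with normalised centroid mu_c is
    ``2 mu_c . x - |mu_c|^2`` (argmax == nearest centroid); a constant
    positive offset keeps the last ReLU inactive, and it cancels in both
    the softmax and the CAM argmax.
    """
    colors = default_class_colors() if class_colors is None else np.asarray(class_colors, float)
    config = config or BackboneConfig()
    model = ConvGapNet(config, seed=0)
    for key in model.params:
        model.params[key] = np.zeros_like(model.params[key])
    k = config.kernel_size
    ctr = k // 2

    # block 0: channels (2j, 2j+1) = (+x_j, -x_j) for j in RGB
    w0 = model.params["conv0_w"]
    for j in range(3):
        w0[2 * j, j, ctr, ctr] = 1.0
        w0[2 * j + 1, j, ctr, ctr] = -1.0

    # blocks 1-2: identity pass-through of the six signed channels
    for name in ("conv1_w", "conv2_w"):
        w = model.params[name]
        for i in range(6):
            w[i, i, ctr, ctr] = 1.0

    # block 3: nearest-centroid scores on channels 0..2, offset positive
    mu = colors / 255.0 - 0.5
    w3, b3 = model.params["conv3_w"], model.params["conv3_b"]
    for c in range(N_CLASSES):
        for j in range(3):
            w3[c, 2 * j, ctr, ctr] = 2.0 * mu[c, j]
            w3[c, 2 * j + 1, ctr, ctr] = -2.0 * mu[c, j]
        b3[c] = -float(mu[c] @ mu[c]) + 3.0

    head = model.params["head_w"]
    for c in range(N_CLASSES):
        head[c, c] = 1.0
    model.history = {"oracle": "hand-set nearest-colour-centroid weights"}
    return model
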