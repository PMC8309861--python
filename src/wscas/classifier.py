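"""Shallow patch classifier: 4 conv blocks + global average pooling head.

The network is a 4-layer CNN (3x3 same-padded convolutions with ReLU),
with 2x2 max-pooling after the first three blocks only, so the final
feature maps have 1/8 of the input resolution and 256 channels.  Global
average pooling (GAP) turns each of the 256 maps f_k(x, y) into one score

    G_k = sum_{x,y} f_k(x, y) / N,

and a bias-free linear layer maps the 256 scores to 3 class logits, which
a softmax converts to probabilities over {background, crop, harvested}.
Keeping the head bias-free means the class activation maps built from the
same weights (see :mod:`wscas.cam`) reproduce the classifier's logits
exactly when averaged over space.

Training follows the patch protocol: random square crops of class-pure
patches, MSE loss between the softmax output and the one-hot label, Adam
at 1e-4, batch size 64, early termination at the lowest validation loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .errors import ModelError

__all__ = [
    "BackboneConfig",
    "TrainConfig",
    "ConvGapNet",
    "build_model",
    "normalize_images",
    "global_average_pool",
    "classify",
    "train_classifier",
    "save_model",
    "load_model",
]

N_CLASSES = 3


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture of the 4-block backbone.

    ``pool_positions`` lists which blocks (0-based) are followed by 2x2
    max-pooling; exactly three of the four, so the output stride is 8.
    """

    conv_channels: tuple = (32, 64, 128, 256)
    kernel_size: int = 3
    pool_positions: tuple = (0, 1, 2)
    input_size: int = 360

    def validate(self) -> None:
        if len(self.conv_channels) != 4:
            raise ModelError("backbone must have exactly 4 conv blocks")
        if self.conv_channels[-1] != 256:
            raise ModelError("final conv block must emit 256 feature maps")
        if len(set(self.pool_positions)) != 3 or not set(self.pool_positions) <= {0, 1, 2, 3}:
            raise ModelError("exactly 3 of the 4 blocks must be pooled (stride 8)")
        if self.kernel_size % 2 != 1:
            raise ModelError("kernel_size must be odd (same padding)")
        if self.input_size % 8 != 0:
            raise ModelError(f"input_size {self.input_size} not divisible by 8")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for the patch classifier."""

    learning_rate: float = 1e-4
    batch_size: int = 64
    patience: int = 10
    max_epochs: int = 200
    crop_size: int | None = None  # defaults to the model input size
    seed: int = 0

    def validate(self) -> None:
        if self.patience < 1 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("patience, batch_size and max_epochs must be >= 1")


def normalize_images(images: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 (or BxHxWx3) -> float32 NCHW in [-0.5, 0.5]."""
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    x = arr.astype(np.float32) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


class ConvGapNet:
    """The backbone + GAP head with explicit numpy parameters.

    Fully convolutional: any input whose sides are divisible by 8 can be
    pushed through, regardless of the size used in training.
    """

    def __init__(self, config: BackboneConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.history: dict | None = None
        rng = np.random.default_rng(seed)
        k = config.kernel_size
        chans = (3,) + tuple(config.conv_channels)
        self.params: dict[str, np.ndarray] = {}
        for i in range(4):
            fan_in = chans[i] * k * k
            std = np.sqrt(2.0 / fan_in)
            self.params[f"conv{i}_w"] = rng.normal(
                0, std, size=(chans[i + 1], chans[i], k, k)
            ).astype(np.float32)
            self.params[f"conv{i}_b"] = np.zeros(chans[i + 1], dtype=np.float32)
        self.params["head_w"] = rng.normal(0, 0.01, size=(N_CLASSES, 256)).astype(np.float32)

    # -- inference ---------------------------------------------------------

    def _check_size(self, x: np.ndarray) -> None:
        h, w = x.shape[2], x.shape[3]
        if h % 8 or w % 8:
            raise ModelError(f"input {h}x{w} not divisible by 8 (three 2x pooling stages)")

    def forward(self, x: np.ndarray, want_caches: bool = False):
        """Run the backbone. Returns (logits, feature_maps[, caches]).

        ``x`` is float32 NCHW; ``feature_maps`` is (B, 256, H/8, W/8).
        """
        self._check_size(x)
        caches = []
        out = x
        for i in range(4):
            out, c_conv = nn.conv2d_forward(
                out, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"]
            )
            out, c_relu = nn.relu_forward(out)
            c_pool = None
            if i in self.config.pool_positions:
                out, c_pool = nn.maxpool2_forward(out)
            if want_caches:
                caches.append((c_conv, c_relu, c_pool))
        maps = out
        gap = global_average_pool(maps)
        logits = gap @ self.params["head_w"].T
        if want_caches:
            return logits, maps, (caches, gap)
        return logits, maps

    def backward(self, dlogits: np.ndarray, maps: np.ndarray, extras) -> dict:
        caches, gap = extras
        grads: dict[str, np.ndarray] = {}
        grads["head_w"] = dlogits.T @ gap
        dgap = dlogits @ self.params["head_w"]
        n_pix = maps.shape[2] * maps.shape[3]
        dmaps = np.broadcast_to(
            dgap[:, :, None, None] / n_pix, maps.shape
        ).astype(np.float32)
        dout = dmaps
        for i in reversed(range(4)):
            c_conv, c_relu, c_pool = caches[i]
            if c_pool is not None:
                dout = nn.maxpool2_backward(dout, c_pool)
            dout = nn.relu_backward(dout, c_relu)
            dout, grads[f"conv{i}_w"], grads[f"conv{i}_b"] = nn.conv2d_backward(dout, c_conv)
        return grads

    def feature_maps(self, image: np.ndarray) -> np.ndarray:
        """Final conv activations f_k for one RGB image -> (256, H/8, W/8)."""
        _, maps = self.forward(normalize_images(image))
        return maps[0]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(normalize_images(images))
        return nn.softmax(logits)

    @property
    def head_weights(self) -> np.ndarray:
        """GAP-to-class weight matrix omega, shape (3, 256), no bias."""
        return self.params["head_w"]

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


def build_model(config: BackboneConfig | None = None, seed: int = 0) -> ConvGapNet:
    """Construct an untrained backbone + GAP head."""
    return ConvGapNet(config or BackboneConfig(), seed=seed)


def global_average_pool(maps: np.ndarray) -> np.ndarray:
    """Spatial mean of each feature map.

    Accepts (K, h, w) or (B, K, h, w); returns (K,) or (B, K).
    """
    maps = np.asarray(maps)
    if maps.ndim not in (3, 4):
        raise ValueError("expected (K, h, w) or (B, K, h, w) feature maps")
    if maps.shape[-1] == 0 or maps.shape[-2] == 0:
        raise ValueError("empty feature map")
    return maps.mean(axis=(-2, -1))


def classify(image: np.ndarray, model: ConvGapNet) -> np.ndarray:
    """Class probabilities (background, crop, harvested) for one image."""
    return model.predict_proba(image)[0]


# -- training -------------------------------------------------------------


def _center_crop(pix: np.ndarray, size: int) -> np.ndarray:
    h, w = pix.shape[:2]
    y0, x0 = (h - size) // 2, (w - size) // 2
    return pix[y0 : y0 + size, x0 : x0 + size]


def train_classifier(split, model: ConvGapNet, config: TrainConfig | None = None):
    """Train on a :class:`~wscas.patches.PatchSplit`; early-terminate at
    the lowest validation loss.

    Each iteration feeds a fresh random square crop of every sampled patch
    (the only augmentation used).  Validation uses deterministic centre
    crops.  Returns ``(model, history)`` where the model carries the
    weights from the epoch with minimum validation loss and ``history``
    has per-epoch ``train_loss``, ``val_loss`` and ``val_acc``.
    """
    from .patches import random_crop_view  # local import to avoid a cycle

    config = config or TrainConfig()
    config.validate()
    crop = config.crop_size or model.config.input_size
    train, val = split.train, split.val
    if not train or not val:
        raise ValueError("both train and val halves must be non-empty")
    for part, name in ((train, "train"), (val, "val")):
        if set(p.label for p in part) != set(range(N_CLASSES)):
            raise ValueError(f"{name} half must contain every class")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    val_x = normalize_images(
        np.stack([_center_crop(p.pixels, crop) for p in val])
    )
    val_y = np.eye(N_CLASSES, dtype=np.float32)[[p.label for p in val]]

    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    best = {"loss": np.inf, "params": model.copy_params(), "epoch": -1}
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train))
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            crops = [
                random_crop_view(train[i], crop, rng=rng) for i in idx
            ]
            x = normalize_images(np.stack(crops))
            y = np.eye(N_CLASSES, dtype=np.float32)[[train[i].label for i in idx]]
            logits, maps, extras = model.forward(x, want_caches=True)
            loss, dlogits = nn.mse_softmax_loss(logits, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})"
                )
            grads = model.backward(dlogits.astype(np.float32), maps, extras)
            opt.step(model.params, grads)
            ep_loss += loss
            n_batches += 1

        vlogits, _ = model.forward(val_x)
        vloss, _ = nn.mse_softmax_loss(vlogits, val_y)
        vacc = float((vlogits.argmax(1) == val_y.argmax(1)).mean())
        history["train_loss"].append(ep_loss / max(n_batches, 1))
        history["val_loss"].append(vloss)
        history["val_acc"].append(vacc)

        if vloss < best["loss"]:
            best = {"loss": vloss, "params": model.copy_params(), "epoch": epoch}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.params = best["params"]
    history["best_epoch"] = best["epoch"]
    model.history = history
    return model, history


# -- checkpointing --------------------------------------------------------


def save_model(model: ConvGapNet, path) -> None:
    """Single-archive checkpoint: weights + architecture + history."""
    meta = {
        "config": asdict(model.config),
        "history": model.history,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_model(path) -> ConvGapNet:
    """Restore a checkpoint; inference is bit-identical to the saved model."""
    with np.load(path) as data:
        try:
            meta = json.loads(bytes(data["__meta__"]).decode())
        except KeyError as exc:
            raise ModelError(f"{path} is not a wscas checkpoint") from exc
        cfg = dict(meta["config"])
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        cfg["pool_positions"] = tuple(cfg["pool_positions"])
        model = ConvGapNet(BackboneConfig(**cfg))
        for key in model.params:
            if key not in data:
                raise ModelError(f"checkpoint missing parameter {key}")
            model.params[key] = data[key].astype(np.float32)
        model.history = meta["history"]
    return model
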