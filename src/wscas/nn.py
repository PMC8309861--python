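"""Minimal CNN primitives in numpy.

Forward and backward passes for stride-1 same-padded convolution, 2x2
max-pooling, ReLU, plus an Adam optimiser — enough to train the shallow
patch classifier on a CPU.  Convolutions are lowered to a single BLAS
matrix product via im2col (``sliding_window_view``), which dominates the
runtime, so everything is kept in float32.

Array layout is NCHW throughout.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv2d_forward",
    "conv2d_backward",
    "maxpool2_forward",
    "maxpool2_backward",
    "relu_forward",
    "relu_backward",
    "softmax",
    "mse_softmax_loss",
    "Adam",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patch matrix, same padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    # (B, C, H, W, k, k) view -> (B, H, W, C, k, k)
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(x.shape[0] * x.shape[2] * x.shape[3], -1)
    return np.ascontiguousarray(cols, dtype=np.float32)


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Stride-1, same-padded convolution.

    x: (B, Cin, H, W); w: (Cout, Cin, k, k); b: (Cout,).
    Returns (out, cache) with out (B, Cout, H, W).
    """
    bsz, cin, h, wd = x.shape
    cout, cin_w, k, _ = w.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, kernel {cin_w}")
    cols = _im2col(x, k)
    wmat = w.reshape(cout, -1)
    out = cols @ wmat.T
    out += b[None, :]
    out = out.reshape(bsz, h, wd, cout).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(out), (cols, w, x.shape)


def conv2d_backward(dout: np.ndarray, cache):
    cols, w, xshape = cache
    bsz, cin, h, wd = xshape
    cout, _, k, _ = w.shape
    dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1).reshape(-1, cout))
    dw = (dmat.T @ cols).reshape(w.shape)
    db = dmat.sum(axis=0)
    dcols = dmat @ w.reshape(cout, -1)  # (B*H*W, Cin*k*k)
    # col2im: scatter-add each of the k*k taps back into the padded input
    p = k // 2
    dxp = np.zeros((bsz, cin, h + 2 * p, wd + 2 * p), dtype=np.float32)
    dcols = dcols.reshape(bsz, h, wd, cin, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    dx = dxp[:, :, p : p + h, p : p + wd]
    return dx, dw, db


def maxpool2_forward(x: np.ndarray):
    """2x2 max-pooling, stride 2. H and W must be even."""
    bsz, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dims")
    xr = x.reshape(bsz, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(bsz, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, xshape = cache
    bsz, c, h, w = xshape
    dxr = np.zeros((bsz, c, h // 2, w // 2, 4), dtype=np.float32)
    np.put_along_axis(dxr, idx[..., None], dout[..., None].astype(np.float32), axis=-1)
    dx = dxr.reshape(bsz, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx.reshape(xshape))


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0)
    return out, x > 0


def relu_backward(dout: np.ndarray, mask):
    return dout * mask


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax with the usual max-shift for stability."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mse_softmax_loss(logits: np.ndarray, onehot: np.ndarray):
    """Mean squared error between softmax probabilities and one-hot targets.

    Returns (loss, dlogits).  The gradient goes through the softmax
    Jacobian: with g = dL/dp, dz_j = p_j (g_j - sum_i g_i p_i).
    """
    p = softmax(logits)
    diff = p - onehot
    loss = float(np.mean(diff**2))
    g = 2.0 * diff / diff.size
    dz = p * (g - (g * p).sum(axis=-1, keepdims=True))
    return loss, dz.astype(np.float32)


class Adam:
    """Adam optimiser over a dict of named parameter arrays."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(params[k].dtype)
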