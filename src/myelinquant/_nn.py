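"""Minimal convolutional-network primitives in numpy.

Implements exactly what the segmentation network needs: strided 2-D
convolution via im2col, its input/weight gradients, transposed (fractional
stride) convolution expressed as the input-gradient of a forward
convolution — which guarantees shape consistency between the down- and
up-sampling arms — plus ReLU, softmax and an Adam optimizer.

Data layout is (N, C, H, W) throughout.  Weights of a convolution mapping
C channels to F filters with k×k kernels are stored as a (C*k*k, F)
matrix plus an (F,) bias.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv_forward",
    "conv_input_grad",
    "conv_weight_grad",
    "im2col",
    "col2im",
    "relu",
    "relu_grad",
    "softmax_channels",
    "Adam",
]

# cache of gather/scatter index tables keyed by geometry
_IDX_CACHE: dict[tuple, np.ndarray] = {}


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _col_indices(c: int, h: int, w: int, k: int, stride: int,
                 pad: int) -> np.ndarray:
    """Flat indices into the padded (C, H+2p, W+2p) volume for im2col.

    Shape (OH*OW, C*k*k): row r lists the source positions of the patch
    feeding output pixel r.
    """
    key = (c, h, w, k, stride, pad)
    if key in _IDX_CACHE:
        return _IDX_CACHE[key]
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    oy = (np.arange(oh) * stride)[:, None, None, None, None]
    ox = (np.arange(ow) * stride)[None, :, None, None, None]
    cc = np.arange(c)[None, None, :, None, None]
    ky = np.arange(k)[None, None, None, :, None]
    kx = np.arange(k)[None, None, None, None, :]
    idx = cc * (hp * wp) + (oy + ky) * wp + (ox + kx)
    idx = idx.reshape(oh * ow, c * k * k)
    _IDX_CACHE[key] = idx
    return idx


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, OH*OW, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k),
                                                   axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, OH, OW, k, k)
    oh, ow = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(cols)


def col2im(cols: np.ndarray, x_shape: tuple[int, int, int, int], k: int,
           stride: int, pad: int) -> np.ndarray:
    """Scatter-add inverse of :func:`im2col` (batched bincount)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    size = c * hp * wp
    bkey = ("batch", n, c, h, w, k, stride, pad)
    if bkey in _IDX_CACHE:
        batch_idx = _IDX_CACHE[bkey]
    else:
        idx = _col_indices(c, h, w, k, stride, pad).ravel()
        batch_idx = (idx[None, :] + (np.arange(n) * size)[:, None]).ravel()
        _IDX_CACHE[bkey] = batch_idx
    out = np.bincount(batch_idx, weights=cols.reshape(-1).astype(np.float64),
                      minlength=n * size)
    out = out.reshape(n, c, hp, wp).astype(cols.dtype)
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None,
                 k: int, stride: int, pad: int,
                 return_cols: bool = False):
    """Strided convolution; returns (N, F, OH, OW) (and cols on request)."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    cols = im2col(x, k, stride, pad)
    y = cols @ weight
    if bias is not None:
        y = y + bias
    y = y.transpose(0, 2, 1).reshape(n, weight.shape[1], oh, ow)
    return (y, cols) if return_cols else y


def conv_input_grad(dy: np.ndarray, weight: np.ndarray,
                    x_shape: tuple[int, int, int, int], k: int, stride: int,
                    pad: int) -> np.ndarray:
    """Gradient of a convolution with respect to its input."""
    n, f = dy.shape[:2]
    dyr = dy.reshape(n, f, -1).transpose(0, 2, 1)  # (N, OH*OW, F)
    dcols = dyr @ weight.T
    return col2im(dcols, x_shape, k, stride, pad)


def conv_weight_grad(cols: np.ndarray, dy: np.ndarray):
    """Gradients (dW, db) given cached im2col patches and output grad."""
    n, f = dy.shape[:2]
    dyr = dy.reshape(n, f, -1).transpose(0, 2, 1)  # (N, OH*OW, F)
    j = cols.shape[2]
    dw = cols.reshape(-1, j).T @ dyr.reshape(-1, f)
    db = dyr.sum(axis=(0, 1))
    return dw, db


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(dy: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dy * (x > 0)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 of (N, K, H, W) logits."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
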