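"""Neural-network layers built on the autodiff Tensor.

Convolutions use an explicit patch-extraction (im2col-style) forward with a
matching scatter-add backward; pooling relies on reshape tricks, so pooled
spatial extents must divide the input. Sizes here are small (clock images
pooled to 64 px before the first convolution), which keeps the pure-NumPy
cost acceptable on one CPU.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Linear", "Conv2d", "Dropout", "avg_pool2d", "global_avg_pool",
           "layer_norm"]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Linear:
    """Affine map x @ W + b on (N, in_features) inputs."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = Tensor(_he_init(rng, (in_features, out_features), in_features),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class Conv2d:
    """3x3-style convolution on NCHW tensors with stride and zero padding."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1, pad: int = 1):
        fan_in = in_ch * kernel * kernel
        self.W = Tensor(_he_init(rng, (out_ch, in_ch, kernel, kernel), fan_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        W, b = self.W, self.b
        k, s, p = self.kernel, self.stride, self.pad
        xd = x.data
        n, c, h, w = xd.shape
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k, k, oh, ow), dtype=xd.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
        out = np.tensordot(cols, W.data, axes=([1, 2, 3], [1, 2, 3]))  # (n,oh,ow,o)
        out = np.moveaxis(out, 3, 1) + b.data[None, :, None, None]

        def bwd(g):  # g: (n, o, oh, ow)
            if W._needs_grad:
                W._accum(np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5])))
            if b._needs_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x._needs_grad:
                dcols = np.tensordot(g, W.data, axes=([1], [0]))  # (n,oh,ow,c,k,k)
                dcols = np.moveaxis(dcols, (3, 4, 5), (1, 2, 3))  # (n,c,k,k,oh,ow)
                dxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, i, j]
                x._accum(dxp[:, :, p:p + h, p:p + w] if p else dxp)

        return Tensor._make(out, (x, W, b), bwd)

    def parameters(self):
        return [self.W, self.b]


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling; spatial dims must divide `factor`."""
    n, c, h, w = x.data.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial size {h}x{w} not divisible by pool factor {factor}")
    oh, ow = h // factor, w // factor
    out = x.data.reshape(n, c, oh, factor, ow, factor).mean(axis=(3, 5))

    def bwd(g):
        if x._needs_grad:
            gg = g[:, :, :, None, :, None] / (factor * factor)
            x._accum(np.broadcast_to(gg, (n, c, oh, factor, ow, factor))
                     .reshape(n, c, h, w).copy())

    return Tensor._make(out, (x,), bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) mean over the spatial grid."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def bwd(g):
        if x._needs_grad:
            x._accum(np.broadcast_to(g[:, :, None, None] / (h * w),
                                     (n, c, h, w)).copy())

    return Tensor._make(out, (x,), bwd)


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample normalization over all non-batch axes (no learned affine).

    Stateless — identical in training and evaluation — which keeps
    inference deterministic without running statistics.
    """
    axes = tuple(range(1, x.data.ndim))
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv
    n = x.data[0].size

    def bwd(g):
        if x._needs_grad:
            gm = g.mean(axis=axes, keepdims=True)
            gym = (g * y).mean(axis=axes, keepdims=True)
            x._accum(inv * (g - gm - y * gym))

    return Tensor._make(y, (x,), bwd)


class Dropout:
    """Inverted dropout; active only when `training` is passed as True."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)
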