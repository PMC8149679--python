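"""Minimal NumPy layer library with explicit forward/backward passes.

Only the pieces the segmentation encoder–decoder needs are implemented:
3x3/1x1 convolutions (im2col + GEMM), group normalization, LeakyReLU,
nearest-neighbour 2x upsampling, residual blocks and sequential containers.
Every layer caches what its backward pass needs; gradients accumulate into
``Param.grad`` and are consumed by an optimizer.

All layers are deterministic in both training and inference mode (group
normalization has no running statistics), which keeps seeded training
bit-reproducible on CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "GroupNorm",
    "LeakyReLU",
    "Upsample2x",
    "Sequential",
    "ResidualBlock",
    "conv_gn_act",
]


class Param:
    """A learnable tensor with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)

    def zero_grad(self) -> None:
        self.grad[...] = 0


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    __call__ = lambda self, x: self.forward(x)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold ``x`` (N,C,H,W) into columns shaped (N, C*k*k, Ho*Wo)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = x.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    sn, sc, sh, sw = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, c, k, k, ho, wo), (sn, sc, sh, sw, sh * stride, sw * stride)
    )
    cols = np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo)
    return cols, (n, c, hp, wp, ho, wo)


class Conv2d(Layer):
    """2D convolution with He (Kaiming) initialization for LeakyReLU fan-in."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 leaky_slope: float = 0.01, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        std = np.sqrt(2.0 / ((1.0 + leaky_slope**2) * fan_in))
        self.w = Param((rng.standard_normal((cout, cin, k, k)) * std).astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.cin:
            raise ValueError(
                f"expected input (N,{self.cin},H,W), got {x.shape}"
            )
        cols, geom = _im2col(x, self.k, self.stride, self.pad)
        n, _, _, _, ho, wo = geom
        w2 = self.w.data.reshape(self.cout, -1)
        out = np.matmul(w2, cols) + self.b.data[:, None]  # (N, F, Ho*Wo)
        self._cache = (cols, geom)
        return out.reshape(n, self.cout, ho, wo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, hp, wp, ho, wo) = self._cache
        d2 = dout.reshape(n, self.cout, ho * wo)
        self.w.grad += np.matmul(d2, cols.transpose(0, 2, 1)).sum(axis=0).reshape(
            self.w.data.shape
        )
        self.b.grad += d2.sum(axis=(0, 2))
        w2 = self.w.data.reshape(self.cout, -1)
        dcols = np.matmul(w2.T, d2).reshape(n, c, self.k, self.k, ho, wo)
        dxp = np.zeros((n, c, hp, wp), dtype=dout.dtype)
        s = self.stride
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, :, di : di + s * ho : s, dj : dj + s * wo : s] += (
                    dcols[:, :, di, dj]
                )
        p = self.pad
        self._cache = None
        return dxp[:, :, p : hp - p, p : wp - p] if p else dxp

    def params(self):
        return [self.w, self.b]


class GroupNorm(Layer):
    def __init__(self, groups: int, channels: int, eps: float = 1e-5, dtype=np.float32):
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.g, self.c, self.eps = groups, channels, eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self._cache = None
        # "capture" records this layer's statistics; "frozen" replays them so
        # a later forward pass is normalized identically to the captured one
        self.capture_stats = False
        self.frozen_stats: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xg = x.reshape(n, self.g, -1)
        if self.frozen_stats is not None and not self.capture_stats:
            mu, inv = self.frozen_stats
        else:
            mu = xg.mean(axis=2, keepdims=True)
            var = xg.var(axis=2, keepdims=True)
            inv = 1.0 / np.sqrt(var + self.eps)
            if self.capture_stats:
                self.frozen_stats = (mu, inv)
        xhat = ((xg - mu) * inv).reshape(n, c, h, w)
        self._cache = (xhat, inv, (n, c, h, w))
        return xhat * self.gamma.data[:, None, None] + self.beta.data[:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, (n, c, h, w) = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = (dout * self.gamma.data[:, None, None]).reshape(n, self.g, -1)
        xh = xhat.reshape(n, self.g, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = (dxhat - m1 - xh * m2) * inv
        self._cache = None
        return dx.reshape(n, c, h, w)

    def params(self):
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dout, self.slope * dout)
        self._mask = None
        return out


class Upsample2x(Layer):
    """Nearest-neighbour upsampling by a factor of two."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def conv_gn_act(cin: int, cout: int, *, k: int = 3, stride: int = 1, pad: int = 1,
                groups: int = 8, slope: float = 0.01, rng=None, dtype=np.float32) -> Sequential:
    g = groups if cout % groups == 0 else 1
    return Sequential(
        Conv2d(cin, cout, k, stride, pad, rng=rng, leaky_slope=slope, dtype=dtype),
        GroupNorm(g, cout, dtype=dtype),
        LeakyReLU(slope),
    )


class ResidualBlock(Layer):
    """Two conv+GN+LeakyReLU stages with an additive skip connection.

    When the channel count changes, the skip path is a 1x1 convolution.
    """

    def __init__(self, cin: int, cout: int, *, groups: int = 8, slope: float = 0.01,
                 rng=None, dtype=np.float32):
        self.branch = Sequential(
            *conv_gn_act(cin, cout, groups=groups, slope=slope, rng=rng, dtype=dtype).layers,
            *conv_gn_act(cout, cout, groups=groups, slope=slope, rng=rng, dtype=dtype).layers,
        )
        self.skip = (
            Conv2d(cin, cout, k=1, stride=1, pad=0, rng=rng, leaky_slope=slope, dtype=dtype)
            if cin != cout
            else None
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        ident = x if self.skip is None else self.skip.forward(x)
        return self.branch.forward(x) + ident

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.branch.backward(dout)
        dx = dx + (dout if self.skip is None else self.skip.backward(dout))
        return dx

    def params(self):
        ps = self.branch.params()
        if self.skip is not None:
            ps += self.skip.params()
        return ps
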