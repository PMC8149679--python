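"""Adam optimizer operating on :class:`~vqradiomics.nn.layers.Param` lists."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    """Adam with float64 moment buffers.

    Group normalization of (near-)constant feature maps — e.g. slices that
    are entirely background — produces legitimately huge raw gradients; the
    squared second moment overflows in float32, so moments are accumulated
    in float64 regardless of the parameter dtype.
    """

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros(p.data.shape, dtype=np.float64) for p in params]
        self.v = [np.zeros(p.data.shape, dtype=np.float64) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64, copy=False)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
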