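"""Vector quantization of encoder latents against a shareable codebook.

The codebook is a K x D matrix of codewords. Each spatial position of an
encoder latent is replaced by its nearest codeword (Euclidean distance,
ties broken toward the lowest index), producing a discrete index grid plus
the looked-up vectors. The latent loss couples encoder and codebook:

    L_latent = ||sg[z_e] - e||^2  +  beta * ||z_e - sg[e]||^2

where ``sg`` is the stop-gradient operator. The first (codebook) term moves
codewords toward the encoder output; the second (commitment) term moves the
encoder output toward its assigned codewords. Both terms use a mean
reduction over all latent elements, so the forward value equals
``(1 + beta) * mean((z_e - z_q)**2)``. The codebook can alternatively be
trained with an exponential moving average of assigned latents, in which
case the codebook term is dropped from the backpropagated objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Codebook",
    "QuantizedLatent",
    "LatentLoss",
    "vector_quantize",
    "latent_loss",
    "latent_loss_grads",
    "ema_update",
]


@dataclass
class Codebook:
    """K x D matrix of shareable feature vectors (codewords)."""

    vectors: np.ndarray
    update_mode: str = "backprop"  # {"backprop", "ema"}
    ema_decay: float = 0.99
    usage_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    # EMA accumulators (cluster sizes and embedding sums)
    ema_cluster_size: np.ndarray = field(default=None)  # type: ignore[assignment]
    ema_sum: np.ndarray = field(default=None)  # type: ignore[assignment]
    ema_eps: float = 1e-5

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 2 or self.K < 2 or self.D < 1:
            raise ValueError("codebook must be K x D with K >= 2, D >= 1")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("codebook vectors must be finite")
        if self.update_mode not in ("backprop", "ema"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")
        if self.update_mode == "ema" and not (0.0 < self.ema_decay < 1.0):
            raise ValueError("ema_decay must lie in (0, 1)")
        if self.usage_counts is None:
            self.usage_counts = np.zeros(self.K, dtype=np.int64)
        if self.ema_cluster_size is None:
            self.ema_cluster_size = np.ones(self.K, dtype=self.vectors.dtype)
        if self.ema_sum is None:
            self.ema_sum = self.vectors.copy()

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    @property
    def D(self) -> int:
        return self.vectors.shape[1]

    @classmethod
    def random(cls, K: int, D: int, rng: np.random.Generator, scale: float = 1.0,
               dtype=np.float32, **kwargs) -> "Codebook":
        vec = (rng.standard_normal((K, D)) * scale / np.sqrt(D)).astype(dtype)
        return cls(vectors=vec, **kwargs)


@dataclass
class QuantizedLatent:
    """Discrete codeword assignment of one latent grid.

    ``indices`` is the W' x H' integer grid; ``values`` holds the looked-up
    codewords, shaped D x W' x H' like the encoder latent.
    """

    indices: np.ndarray
    values: np.ndarray


def _nearest_codeword(flat: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    # squared Euclidean distances via expansion; argmin takes the lowest
    # index among exact ties.
    d = (
        np.einsum("md,md->m", flat, flat)[:, None]
        - 2.0 * flat @ vectors.T
        + np.einsum("kd,kd->k", vectors, vectors)[None, :]
    )
    return np.argmin(d, axis=1)


def vector_quantize(latent: np.ndarray, codebook: Codebook,
                    count_usage: bool = True) -> QuantizedLatent:
    """Nearest-neighbour lookup of every latent position on the codebook.

    ``latent`` is a D x W' x H' array (a single latent grid).
    """
    latent = np.asarray(latent)
    if latent.ndim != 3 or latent.shape[0] != codebook.D:
        raise ValueError(
            f"latent must be D x W' x H' with D={codebook.D}, got {latent.shape}"
        )
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent contains non-finite values")
    d, wp, hp = latent.shape
    flat = latent.reshape(d, -1).T  # (M, D)
    idx = _nearest_codeword(flat, codebook.vectors.astype(latent.dtype, copy=False))
    if count_usage:
        np.add.at(codebook.usage_counts, idx, 1)
    values = codebook.vectors[idx].T.reshape(d, wp, hp).astype(latent.dtype, copy=False)
    return QuantizedLatent(indices=idx.reshape(wp, hp), values=values)


@dataclass
class LatentLoss:
    codebook_term: float
    commitment_term: float

    @property
    def total(self) -> float:
        return self.codebook_term + self.commitment_term


def latent_loss(latent: np.ndarray, quantized: QuantizedLatent, beta: float) -> LatentLoss:
    """Forward value of the latent loss (mean reduction over all elements)."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    ze = np.asarray(latent, dtype=np.float64)
    zq = np.asarray(quantized.values, dtype=np.float64)
    if ze.shape != zq.shape:
        raise ValueError("latent and quantized shapes differ")
    mse = float(np.mean((ze - zq) ** 2))
    return LatentLoss(codebook_term=mse, commitment_term=beta * mse)


def latent_loss_grads(latent: np.ndarray, quantized: QuantizedLatent, beta: float,
                      K: int) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the latent loss honouring the stop-gradient routing.

    Returns ``(d_ze, d_codebook)``: the commitment gradient reaching the
    encoder output, and the codebook-term gradient accumulated per codeword
    (zero rows for unassigned codewords).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    ze = np.asarray(latent)
    zq = quantized.values
    m = ze.size
    diff = ze - zq
    d_ze = (2.0 * beta / m) * diff
    dim = ze.shape[-3]  # works for single grids and batches alike
    d_cb = np.zeros((K, dim), dtype=ze.dtype)
    flat_diff = np.moveaxis(diff, -3, -1).reshape(-1, dim)  # = ze - e per site
    np.add.at(d_cb, quantized.indices.ravel(), (-2.0 / m) * flat_diff)
    return d_ze, d_cb


def ema_update(codebook: Codebook, latent: np.ndarray, assignments: np.ndarray) -> Codebook:
    """One exponential-moving-average codebook update.

    Cluster-size and embedding-sum accumulators are decayed and refreshed
    from the current assignments; codewords become smoothed sum / smoothed
    count (Laplace smoothing keeps unassigned codewords in place).
    """
    if codebook.update_mode != "ema":
        raise ValueError("codebook update_mode is not 'ema'")
    gamma = codebook.ema_decay
    ze = np.asarray(latent)
    flat = ze.reshape(ze.shape[0], -1).T  # (M, D)
    idx = np.asarray(assignments).ravel()
    K = codebook.K
    n_k = np.bincount(idx, minlength=K).astype(codebook.vectors.dtype)
    sum_k = np.zeros_like(codebook.ema_sum)
    np.add.at(sum_k, idx, flat.astype(sum_k.dtype, copy=False))
    codebook.ema_cluster_size = gamma * codebook.ema_cluster_size + (1 - gamma) * n_k
    codebook.ema_sum = gamma * codebook.ema_sum + (1 - gamma) * sum_k
    total = codebook.ema_cluster_size.sum()
    smoothed = (
        (codebook.ema_cluster_size + codebook.ema_eps)
        / (total + K * codebook.ema_eps)
        * total
    )
    codebook.vectors = (codebook.ema_sum / smoothed[:, None]).astype(
        codebook.vectors.dtype, copy=False
    )
    return codebook
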