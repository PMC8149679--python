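"""Encoder–decoder segmentation network with a vector-quantized bottleneck.

The encoder is a stack of residual blocks (two conv + group norm + LeakyReLU
stages with a skip connection), each followed by a stride-2 downsampling
convolution except the last, and a final 1x1 projection onto the codeword
dimension D. The decoder mirrors it: a 1x1 projection from D, residual
blocks preceded by nearest-neighbour upsampling + convolution stages, and a
1x1 head producing one logit channel per segmentation label. Between the
two sits the codebook: every spatial latent vector is replaced by its
nearest codeword, and gradients from the decoder are passed straight
through the quantization to the encoder output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .losses import segmentation_loss_grad, soft_dice_loss, focal_loss
from .nn.layers import Conv2d, Param, ResidualBlock, Sequential, Upsample2x, conv_gn_act
from .vq import Codebook, QuantizedLatent, ema_update, latent_loss, latent_loss_grads

__all__ = [
    "NetworkConfig",
    "SegmentationOutput",
    "VQSegNet",
    "FULL_SCALE_CONFIG",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    channels_in: int = 4
    n_labels: int = 4
    encoder_filters: tuple[int, ...] = (32, 64, 128, 128, 128, 128)
    decoder_filters: tuple[int, ...] = (128, 128, 128, 128, 64, 32)
    codebook_K: int = 512
    codebook_D: int = 64
    commitment_beta: float = 0.25
    groupnorm_groups: int = 8
    leaky_slope: float = 0.01
    codebook_update: str = "backprop"  # {"backprop", "ema"}
    ema_decay: float = 0.99
    focal_gamma: float = 2.0
    dice_eps: float = 1e-5

    def __post_init__(self):
        self.encoder_filters = tuple(self.encoder_filters)
        self.decoder_filters = tuple(self.decoder_filters)
        if len(self.encoder_filters) != len(self.decoder_filters):
            raise ValueError("encoder and decoder filter lists must have equal length")
        if self.commitment_beta < 0:
            raise ValueError("commitment_beta must be non-negative")

    @property
    def n_downsamples(self) -> int:
        return len(self.encoder_filters) - 1

    @property
    def reduction(self) -> int:
        return 2**self.n_downsamples


FULL_SCALE_CONFIG = NetworkConfig()
"""Full-scale configuration: 4 x 256 x 256 input, latent 64 x 8 x 8, K = 512."""


@dataclass
class SegmentationOutput:
    """Decoder output: per-label logit map and its argmax label map."""

    logits: np.ndarray  # S x W x H
    label_map: np.ndarray  # W x H integers


class VQSegNet:
    """Segmentation network whose bottleneck codewords are shareable features."""

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = config
        enc: list = []
        cur = c.channels_in
        for i, f in enumerate(c.encoder_filters):
            enc.append(ResidualBlock(cur, f, groups=c.groupnorm_groups,
                                     slope=c.leaky_slope, rng=rng, dtype=dtype))
            cur = f
            if i < len(c.encoder_filters) - 1:
                enc.append(conv_gn_act(cur, cur, stride=2, groups=c.groupnorm_groups,
                                       slope=c.leaky_slope, rng=rng, dtype=dtype))
        enc.append(Conv2d(cur, c.codebook_D, k=1, stride=1, pad=0, rng=rng,
                          leaky_slope=c.leaky_slope, dtype=dtype))
        self.encoder = Sequential(*enc)

        dec: list = [Conv2d(c.codebook_D, c.decoder_filters[0], k=1, stride=1, pad=0,
                            rng=rng, leaky_slope=c.leaky_slope, dtype=dtype)]
        cur = c.decoder_filters[0]
        for i, f in enumerate(c.decoder_filters):
            if i > 0:
                dec.append(Upsample2x())
                dec.append(conv_gn_act(cur, f, groups=c.groupnorm_groups,
                                       slope=c.leaky_slope, rng=rng, dtype=dtype))
                cur = f
            dec.append(ResidualBlock(cur, f, groups=c.groupnorm_groups,
                                     slope=c.leaky_slope, rng=rng, dtype=dtype))
            cur = f
        dec.append(Conv2d(cur, c.n_labels, k=1, stride=1, pad=0, rng=rng,
                          leaky_slope=c.leaky_slope, dtype=dtype))
        self.decoder = Sequential(*dec)

        self.codebook = Codebook.random(
            c.codebook_K, c.codebook_D, rng, dtype=dtype,
            update_mode=c.codebook_update, ema_decay=c.ema_decay,
        )
        self._cb_param = Param(self.codebook.vectors)

    # ------------------------------------------------------------------ #

    def params(self) -> list[Param]:
        ps = self.encoder.params() + self.decoder.params()
        if self.codebook.update_mode == "backprop":
            ps.append(self._cb_param)
        return ps

    def _check_spatial(self, shape):
        r = self.config.reduction
        if shape[-2] % r or shape[-1] % r:
            raise ValueError(
                f"spatial size {shape[-2:]} not divisible by reduction factor {r}"
            )

    def encode(self, image: np.ndarray) -> np.ndarray:
        """Map a C x W x H slice (or an N x C x W x H batch) to its latent z_e."""
        image = np.asarray(image, dtype=self.dtype)
        single = image.ndim == 3
        x = image[None] if single else image
        if x.shape[1] != self.config.channels_in:
            raise ValueError(
                f"expected {self.config.channels_in} channels, got {x.shape[1]}"
            )
        self._check_spatial(x.shape)
        z = self.encoder.forward(x)
        return z[0] if single else z

    def quantize(self, latent: np.ndarray, count_usage: bool = True) -> QuantizedLatent:
        return vector_quantize_batch(latent, self.codebook, count_usage=count_usage)

    def decode(self, quantized: np.ndarray | QuantizedLatent) -> SegmentationOutput:
        """Decode a D x W' x H' quantized latent into a logit map + labels."""
        values = quantized.values if isinstance(quantized, QuantizedLatent) else quantized
        values = np.asarray(values, dtype=self.dtype)
        single = values.ndim == 3
        x = values[None] if single else values
        if x.shape[1] != self.config.codebook_D:
            raise ValueError(
                f"expected latent dimension {self.config.codebook_D}, got {x.shape[1]}"
            )
        logits = self.decoder.forward(x)
        if single:
            logits = logits[0]
            return SegmentationOutput(logits=logits, label_map=np.argmax(logits, axis=0))
        return SegmentationOutput(logits=logits, label_map=np.argmax(logits, axis=1))

    def _decoder_groupnorms(self):
        stack = list(self.decoder.layers)
        out = []
        while stack:
            layer = stack.pop()
            if isinstance(layer, Sequential):
                stack.extend(layer.layers)
            elif isinstance(layer, ResidualBlock):
                stack.append(layer.branch)
                if layer.skip is not None:
                    stack.append(layer.skip)
            elif hasattr(layer, "frozen_stats"):
                out.append(layer)
        return out

    def capture_decoder_stats(self):
        """Context manager: record decoder normalization statistics.

        Inside the context, a decode records each group-norm layer's
        statistics; afterwards every decode replays them, so two latents
        are decoded under identical normalization (used for controlled
        codeword ablation). Call :meth:`clear_decoder_stats` to return to
        ordinary behaviour.
        """
        net = self

        class _Capture:
            def __enter__(self):
                for gn in net._decoder_groupnorms():
                    gn.capture_stats = True

            def __exit__(self, *exc):
                for gn in net._decoder_groupnorms():
                    gn.capture_stats = False

        return _Capture()

    def clear_decoder_stats(self) -> None:
        for gn in self._decoder_groupnorms():
            gn.frozen_stats = None
            gn.capture_stats = False

    def segment(self, image: np.ndarray) -> SegmentationOutput:
        """Full inference pass: encode, quantize, decode."""
        z = self.encode(image)
        q = self.quantize(z, count_usage=False)
        return self.decode(q)

    # ------------------------------------------------------------------ #

    def train_step(self, images: np.ndarray, labels: np.ndarray, optimizer) -> dict:
        """One forward/backward/update pass on a minibatch.

        Gradient routing: the decoder gradient reaches the encoder output
        straight through the quantization; the commitment term adds its own
        encoder-side gradient; the codebook term updates only the codebook
        (via backprop or an EMA step depending on the update mode).
        Returns the loss components and distinct-codeword usage of the batch.
        """
        c = self.config
        x = np.asarray(images, dtype=self.dtype)
        y = np.asarray(labels)
        ze = self.encoder.forward(x)
        q = self.quantize(ze)
        lat = latent_loss(ze, q, c.commitment_beta)
        logits = self.decoder.forward(q.values)
        seg_dice = soft_dice_loss(logits, y, eps=c.dice_eps)
        seg_focal = focal_loss(logits, y, gamma=c.focal_gamma)
        dlogits = segmentation_loss_grad(logits, y, gamma=c.focal_gamma, eps=c.dice_eps)
        optimizer.zero_grad()
        dzq = self.decoder.backward(dlogits)
        d_ze, d_cb = latent_loss_grads(ze, q, c.commitment_beta, c.codebook_K)
        if self.codebook.update_mode == "backprop":
            self._cb_param.grad += d_cb
        else:
            ema_update(self.codebook, ze, q.indices)
        self.encoder.backward(dzq + d_ze)
        optimizer.step()
        return {
            "latent_loss": lat.total,
            "codebook_loss": lat.codebook_term,
            "commitment_loss": lat.commitment_term,
            "dice_loss": seg_dice,
            "focal_loss": seg_focal,
            "segmentation_loss": seg_dice + seg_focal,
            "total_loss": lat.total + seg_dice + seg_focal,
            "codewords_used": int(np.unique(q.indices).size),
        }


def vector_quantize_batch(latent: np.ndarray, codebook: Codebook,
                          count_usage: bool = True) -> QuantizedLatent:
    """Batched nearest-codeword lookup; accepts D x W' x H' or N x D x W' x H'."""
    from .vq import _nearest_codeword

    latent = np.asarray(latent)
    single = latent.ndim == 3
    z = latent[None] if single else latent
    n, d, wp, hp = z.shape
    if d != codebook.D:
        raise ValueError(f"latent dimension {d} != codebook D {codebook.D}")
    if not np.all(np.isfinite(z)):
        raise ValueError("latent contains non-finite values")
    flat = z.transpose(0, 2, 3, 1).reshape(-1, d)
    idx = _nearest_codeword(flat, codebook.vectors.astype(z.dtype, copy=False))
    if count_usage:
        np.add.at(codebook.usage_counts, idx, 1)
    values = (
        codebook.vectors[idx]
        .reshape(n, wp, hp, d)
        .transpose(0, 3, 1, 2)
        .astype(z.dtype, copy=False)
    )
    indices = idx.reshape(n, wp, hp)
    if single:
        return QuantizedLatent(indices=indices[0], values=values[0])
    return QuantizedLatent(indices=indices, values=values)


# ---------------------------------------------------------------------- #
# checkpointing


def save_checkpoint(path, net: VQSegNet, extra: dict | None = None) -> None:
    """Serialize weights, codebook, config and seed into a single archive."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(
        net.encoder.params() + net.decoder.params())}
    arrays["codebook_vectors"] = net.codebook.vectors
    arrays["codebook_usage"] = net.codebook.usage_counts
    arrays["ema_cluster_size"] = net.codebook.ema_cluster_size
    arrays["ema_sum"] = net.codebook.ema_sum
    meta = {"config": asdict(net.config), "seed": net.seed}
    if extra:
        meta["extra"] = extra
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path) -> VQSegNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        cfg = NetworkConfig(**meta["config"])
        net = VQSegNet(cfg, seed=meta["seed"])
        for i, p in enumerate(net.encoder.params() + net.decoder.params()):
            arr = z[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint/config mismatch")
            p.data[...] = arr
        net.codebook.vectors[...] = z["codebook_vectors"]
        net.codebook.usage_counts = z["codebook_usage"].copy()
        net.codebook.ema_cluster_size = z["ema_cluster_size"].copy()
        net.codebook.ema_sum = z["ema_sum"].copy()
    return net
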