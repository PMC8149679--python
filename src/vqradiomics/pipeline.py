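"""Preprocessing, augmentation, training loop and Dice evaluation.

Volumes are decomposed into 2D axial slices. Z-score normalization uses
per-volume, per-channel statistics over non-background voxels only, so the
exact-zero background of skull-stripped (and phantom) volumes stays at
zero. Training minimizes latent loss + segmentation loss with Adam over
shuffled minibatches; everything is reproducible given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .network import NetworkConfig, VQSegNet
from .nn.optim import Adam
from .phantom import LabeledVolume, background_mask

__all__ = [
    "AugmentFlags",
    "TrainConfig",
    "PreprocessedVolume",
    "DiceReport",
    "preprocess_volume",
    "augment",
    "train_segmentation",
    "predict_volume",
    "dice_evaluate",
    "dice_coefficient",
]

_STD_FLOOR = 1e-6


@dataclass
class AugmentFlags:
    hflip: bool = True
    rotate: bool = True
    intensity_shift: bool = True
    intensity_scale: bool = True

    @property
    def any(self) -> bool:
        return self.hflip or self.rotate or self.intensity_shift or self.intensity_scale


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 72
    max_epochs: int = 600
    optimizer: str = "adam"
    seed: int = 0
    augmentations: AugmentFlags = field(default_factory=AugmentFlags)
    #: train on every axial slice, or drop slices with no foreground at all
    #: (tumor-bearing slices are still dominated by background pixels)
    keep_empty_slices: bool = True
    #: initialize the codebook by k-means over encoder latents of the
    #: training set before the first step; with a small codebook this
    #: spreads codewords over the latent manifold instead of letting the
    #: (hugely over-represented) background claim nearly all of them
    codebook_kmeans_init: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if isinstance(self.augmentations, dict):
            self.augmentations = AugmentFlags(**self.augmentations)


@dataclass
class PreprocessedVolume:
    """Per-slice arrays of one normalized volume (slice axis first)."""

    images: np.ndarray  # I x C x W x H
    labels: np.ndarray | None  # I x W x H
    foreground: np.ndarray  # I x W x H bool
    volume_id: str
    grade: int | None

    def __len__(self) -> int:
        return self.images.shape[0]

    def __iter__(self):
        labels = [None] * len(self) if self.labels is None else self.labels
        return iter(zip(self.images, labels))


def _resize_slice(arr: np.ndarray, target: tuple[int, int], order: int) -> np.ndarray:
    zoom = (target[0] / arr.shape[0], target[1] / arr.shape[1])
    if zoom == (1.0, 1.0):
        return arr
    return ndimage.zoom(arr, zoom, order=order, mode="nearest", grid_mode=True)


def preprocess_volume(volume: LabeledVolume, target_size: tuple[int, int] | None = None
                      ) -> PreprocessedVolume:
    """Z-score normalize over non-background voxels and emit axial slices.

    Images are resized bilinearly, labels with nearest-neighbour
    interpolation (so no new label values appear). Background voxels remain
    exactly zero after normalization.
    """
    img = np.asarray(volume.image, dtype=np.float32)
    fg = ~background_mask(img)
    norm = np.zeros_like(img)
    for c in range(img.shape[0]):
        vals = img[c][fg]
        mu = float(vals.mean()) if vals.size else 0.0
        sd = float(vals.std()) if vals.size else 0.0
        if sd < _STD_FLOOR:
            warnings.warn(
                f"channel {c} of {volume.volume_id} has (near-)constant intensity; "
                "flooring std", RuntimeWarning, stacklevel=2)
            sd = _STD_FLOOR
        norm[c][fg] = (img[c][fg] - mu) / sd

    n_slices = img.shape[-1]
    w, h = img.shape[1:3]
    target = target_size or (w, h)
    images = np.zeros((n_slices, img.shape[0]) + tuple(target), dtype=np.float32)
    fgmask = np.zeros((n_slices,) + tuple(target), dtype=bool)
    labels = None
    if volume.labels is not None:
        labels = np.zeros((n_slices,) + tuple(target), dtype=np.int16)
    for i in range(n_slices):
        for c in range(img.shape[0]):
            images[i, c] = _resize_slice(norm[c, :, :, i], target, order=1)
        fgmask[i] = _resize_slice(fg[:, :, i].astype(np.float32), target, order=0) > 0.5
        images[i][:, ~fgmask[i]] = 0.0
        if labels is not None:
            labels[i] = _resize_slice(volume.labels[:, :, i], target, order=0)
    return PreprocessedVolume(images=images, labels=labels, foreground=fgmask,
                              volume_id=volume.volume_id, grade=volume.grade)


def augment(image_slice: np.ndarray, label: np.ndarray | None, flags: AugmentFlags,
            rng: np.random.Generator):
    """Jointly transform one slice and its label map.

    Geometric operations (flip, rotation) apply to image and label alike;
    intensity shift/scale apply to foreground image voxels only.
    """
    img = image_slice
    lab = label
    if flags.hflip and rng.random() < 0.5:
        img = img[:, :, ::-1].copy()
        lab = None if lab is None else lab[:, ::-1].copy()
    if flags.rotate:
        angle = float(rng.uniform(-15.0, 15.0))
        img = np.stack([
            ndimage.rotate(ch, angle, reshape=False, order=1, mode="constant")
            for ch in img
        ])
        if lab is not None:
            lab = ndimage.rotate(lab, angle, reshape=False, order=0, mode="constant")
    if flags.intensity_shift or flags.intensity_scale:
        img = img.copy()
        fg = np.any(img != 0, axis=0)
        if flags.intensity_scale:
            img[:, fg] *= 1.0 + rng.uniform(-0.1, 0.1)
        if flags.intensity_shift:
            img[:, fg] += rng.uniform(-0.1, 0.1)
    return img, lab


def _kmeans_init_codebook(net: VQSegNet, images: np.ndarray, seed: int,
                          max_slices: int = 64) -> None:
    """Set the codebook to k-means centroids of initial encoder latents."""
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    sel = rng.permutation(images.shape[0])[:max_slices]
    z = net.encode(images[sel])  # (n, D, W', H')
    flat = np.moveaxis(z, 1, -1).reshape(-1, net.codebook.D).astype(np.float64)
    k = net.codebook.K
    if flat.shape[0] < k:  # pragma: no cover - degenerate tiny inputs
        return
    km = KMeans(n_clusters=k, n_init=1, max_iter=25, random_state=seed % (2**31))
    km.fit(flat)
    net.codebook.vectors[...] = km.cluster_centers_.astype(
        net.codebook.vectors.dtype)
    net.codebook.ema_sum = net.codebook.vectors.copy()
    net.codebook.ema_cluster_size = np.ones(k, dtype=net.codebook.vectors.dtype)


def train_segmentation(dataset: list[LabeledVolume], net_config: NetworkConfig,
                       train_config: TrainConfig,
                       target_size: tuple[int, int] | None = None,
                       net: VQSegNet | None = None,
                       log_fn=None) -> tuple[VQSegNet, list[dict]]:
    """Train the segmentation network; returns (network, per-epoch history).

    Passing an existing ``net`` continues training it (e.g. a refinement
    phase on a different slice subset) with a fresh optimizer state.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    pre = [preprocess_volume(v, target_size) for v in dataset]
    if any(p.labels is None for p in pre):
        raise ValueError("training requires labelled volumes")
    images = np.concatenate([p.images for p in pre], axis=0)
    labels = np.concatenate([p.labels for p in pre], axis=0)
    if not train_config.keep_empty_slices:
        keep = np.concatenate([p.foreground.any(axis=(1, 2)) for p in pre])
        if keep.any():
            images, labels = images[keep], labels[keep]
    if labels.max() >= net_config.n_labels:
        raise ValueError("label value outside configured number of labels")

    fresh = net is None
    if fresh:
        net = VQSegNet(net_config, seed=train_config.seed)
    if fresh and train_config.codebook_kmeans_init:
        _kmeans_init_codebook(net, images, train_config.seed)
    opt = Adam(net.params(), lr=train_config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([train_config.seed, 7]))
    n = images.shape[0]
    bs = min(train_config.batch_size, n)
    history: list[dict] = []
    for epoch in range(train_config.max_epochs):
        order = rng.permutation(n)
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, bs):
            sel = order[start : start + bs]
            xb = images[sel]
            yb = labels[sel]
            if train_config.augmentations.any:
                xs, ys = [], []
                for x, y in zip(xb, yb):
                    x2, y2 = augment(x, y, train_config.augmentations, rng)
                    xs.append(x2)
                    ys.append(y2)
                xb = np.stack(xs)
                yb = np.stack(ys)
            metrics = net.train_step(xb, yb, opt)
            if not np.isfinite(metrics["total_loss"]):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: {metrics}"
                )
            for k, v in metrics.items():
                if k != "codewords_used":
                    sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
        row = {"epoch": epoch, **{k: v / n_batches for k, v in sums.items()},
               "codewords_used": int((net.codebook.usage_counts > 0).sum())}
        history.append(row)
        if log_fn is not None:
            log_fn(row)
    return net, history


def predict_volume(net: VQSegNet, volume: LabeledVolume | PreprocessedVolume,
                   target_size: tuple[int, int] | None = None) -> np.ndarray:
    """Segment every slice of a volume; returns a W x H x I label array."""
    pre = volume if isinstance(volume, PreprocessedVolume) else preprocess_volume(
        volume, target_size)
    out = net.decode(net.quantize(net.encode(pre.images), count_usage=False))
    return np.moveaxis(out.label_map, 0, -1)


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """2|P∩G| / (|P|+|G|); defined as 1.0 when both masks are empty."""
    p = int(pred_mask.sum())
    g = int(true_mask.sum())
    if p + g == 0:
        return 1.0
    return 2.0 * int((pred_mask & true_mask).sum()) / (p + g)


_REGIONS = {
    "NET": (1,),
    "ED": (2,),
    "ET": (3,),
    "tumor_core": (1, 3),
    "whole_tumor": (1, 2, 3),
}


@dataclass
class DiceReport:
    """Per-region Dice scores: per-volume values plus mean and std."""

    per_volume: dict[str, np.ndarray]
    mean: dict[str, float]
    std: dict[str, float]

    def summary(self) -> dict[str, str]:
        return {k: f"{self.mean[k]:.3f} ± {self.std[k]:.3f}" for k in self.mean}


def dice_evaluate(predictions: list[np.ndarray], ground_truths: list[np.ndarray],
                  n_labels: int = 4) -> DiceReport:
    """Dice per label (NET, ED, ET) and for the composite regions.

    Composite regions (tumor core = NET+ET, whole tumor = NET+ED+ET) are
    evaluated on unioned masks, not by averaging per-label Dice.
    """
    if len(predictions) != len(ground_truths):
        raise ValueError("prediction/ground-truth count mismatch")
    per: dict[str, list[float]] = {k: [] for k in _REGIONS}
    for p, g in zip(predictions, ground_truths):
        if p.shape != g.shape:
            raise ValueError("shape mismatch between prediction and ground truth")
        if int(np.max(g)) >= n_labels or int(np.max(p)) >= n_labels:
            raise ValueError("label value outside the configured label set")
        for name, labels in _REGIONS.items():
            pm = np.isin(p, labels)
            gm = np.isin(g, labels)
            per[name].append(dice_coefficient(pm, gm))
    arrays = {k: np.asarray(v) for k, v in per.items()}
    return DiceReport(
        per_volume=arrays,
        mean={k: float(v.mean()) for k, v in arrays.items()},
        std={k: float(v.std()) for k, v in arrays.items()},
    )
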