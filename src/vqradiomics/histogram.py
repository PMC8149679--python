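"""Volume-level codeword histograms and intensity-perturbation robustness.

A volume's histogram counts how often each codeword appears across the
quantized latent grids of all its axial slices, so the counts always sum
to I * W' * H'. Robustness is probed by perturbing the (already Z-score
normalized) foreground intensities — shift ``x + m`` or scale
``x * (1 + m)`` — and measuring the *difference ratio*: the summed absolute
change in per-codeword counts divided by the total count of the original
histogram. A magnitude of 0 is the identity, giving a ratio of exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import VQSegNet
from .phantom import LabeledVolume
from .pipeline import PreprocessedVolume, preprocess_volume

__all__ = [
    "HistogramFeature",
    "PerturbationSpec",
    "DifferenceRatioResult",
    "extract_histogram",
    "apply_perturbation",
    "difference_ratio",
    "robustness_sweep",
    "DEFAULT_MAGNITUDES",
]

DEFAULT_MAGNITUDES = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass
class HistogramFeature:
    """Length-K codeword occurrence counts for one volume."""

    counts: np.ndarray
    volume_id: str
    n_slices: int
    latent_positions_per_slice: int
    grade: int | None = None
    indices: np.ndarray | None = None  # optional per-slice index grids (I, W', H')

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PerturbationSpec:
    kind: str  # {"scale", "shift"}
    magnitude: float

    def __post_init__(self):
        if self.kind not in ("scale", "shift"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("magnitude must lie in [0, 1]")


def apply_perturbation(volume: PreprocessedVolume, spec: PerturbationSpec
                       ) -> PreprocessedVolume:
    """Perturb foreground intensities of a normalized volume.

    shift: x' = x + m;  scale: x' = x * (1 + m). Background voxels are
    untouched; magnitude 0 returns the data unchanged.
    """
    images = volume.images.copy()
    fg = volume.foreground
    for i in range(images.shape[0]):
        if spec.kind == "shift":
            images[i][:, fg[i]] += spec.magnitude
        else:
            images[i][:, fg[i]] *= 1.0 + spec.magnitude
    return PreprocessedVolume(images=images, labels=volume.labels,
                              foreground=fg, volume_id=volume.volume_id,
                              grade=volume.grade)


def extract_histogram(volume: LabeledVolume | PreprocessedVolume, net: VQSegNet,
                      perturbation: PerturbationSpec | None = None,
                      target_size: tuple[int, int] | None = None,
                      keep_indices: bool = False) -> HistogramFeature:
    """Encode and quantize every slice; count codeword occurrences."""
    pre = volume if isinstance(volume, PreprocessedVolume) else preprocess_volume(
        volume, target_size)
    if pre.images.shape[1] != net.config.channels_in:
        raise ValueError(
            f"volume has {pre.images.shape[1]} channels, network expects "
            f"{net.config.channels_in}"
        )
    if perturbation is not None:
        pre = apply_perturbation(pre, perturbation)
    q = net.quantize(net.encode(pre.images), count_usage=False)
    counts = np.bincount(q.indices.ravel(), minlength=net.codebook.K).astype(np.int64)
    return HistogramFeature(
        counts=counts,
        volume_id=pre.volume_id,
        n_slices=pre.images.shape[0],
        latent_positions_per_slice=int(np.prod(q.indices.shape[1:])),
        grade=pre.grade,
        indices=q.indices.copy() if keep_indices else None,
    )


def difference_ratio(original: HistogramFeature, perturbed: HistogramFeature,
                     denominator: str = "total") -> float:
    """Sum_k |c_k - c'_k| normalized by the original histogram.

    ``denominator="total"`` (default) divides by the total codeword
    occurrences of the original histogram (= number of latent positions),
    so the unperturbed ratio is exactly 0; ``"distinct"`` divides by the
    number of distinct codewords present instead.
    """
    if original.K != perturbed.K:
        raise ValueError("histograms have different codebook sizes")
    if original.volume_id != perturbed.volume_id:
        raise ValueError("histograms belong to different volumes")
    num = int(np.abs(original.counts - perturbed.counts).sum())
    if denominator == "total":
        den = original.total
    elif denominator == "distinct":
        den = int((original.counts > 0).sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if den == 0:
        raise ValueError("original histogram is empty")
    return num / den


@dataclass
class DifferenceRatioResult:
    kind: str
    magnitude: float
    ratios: np.ndarray  # per volume
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self):
        self.mean = float(np.mean(self.ratios))
        self.std = float(np.std(self.ratios))


def robustness_sweep(volumes: list[LabeledVolume | PreprocessedVolume], net: VQSegNet,
                     kinds: tuple[str, ...] = ("scale", "shift"),
                     magnitudes: tuple[float, ...] = DEFAULT_MAGNITUDES,
                     target_size: tuple[int, int] | None = None
                     ) -> list[DifferenceRatioResult]:
    """Difference-ratio curves (mean ± std across volumes) per perturbation."""
    if not volumes:
        raise ValueError("no volumes supplied")
    if not any(m == 0.0 for m in magnitudes):
        raise ValueError("magnitudes must include 0.0")
    pres = [
        v if isinstance(v, PreprocessedVolume) else preprocess_volume(v, target_size)
        for v in volumes
    ]
    originals = [extract_histogram(p, net) for p in pres]
    results = []
    for kind in kinds:
        for mag in magnitudes:
            spec = PerturbationSpec(kind=kind, magnitude=float(mag))
            ratios = np.array([
                difference_ratio(orig, extract_histogram(p, net, perturbation=spec))
                for p, orig in zip(pres, originals)
            ])
            results.append(DifferenceRatioResult(kind=kind, magnitude=float(mag),
                                                 ratios=ratios))
    return results


def sweep_to_frame(results: list[DifferenceRatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"kind": r.kind, "magnitude": r.magnitude, "mean": r.mean, "std": r.std}
         for r in results]
    )
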