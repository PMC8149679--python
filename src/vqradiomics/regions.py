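"""Feature-ablation maps: which image regions does a codeword encode?

A codeword's *responsible region* is obtained by decoding a slice's
quantized latent twice — once as-is, once with every occurrence of the
codeword replaced by the *background vector* (the modal codeword over
latent positions whose receptive footprint lies outside the body) — and
taking the per-pixel L1 difference between the two logit maps. If the
codeword does not occur in the grid (or equals the background vector) the
map is exactly zero. Maps of several codewords aggregate additively.

Per-label overlap statistics (sums of raw map values within each
ground-truth label, compared across labels with Kruskal–Wallis plus Dunn's
all-pairs post-hoc test) quantify which tumor sub-region a responsible
region concentrates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import VQSegNet
from .phantom import LabeledVolume
from .pipeline import PreprocessedVolume, preprocess_volume
from .stats import DunnResult, dunn_test
from .vq import QuantizedLatent

__all__ = [
    "BackgroundVector",
    "ResponsibleRegionMap",
    "RegionOverlapStats",
    "find_background_vector",
    "background_codewords",
    "ablate_codeword",
    "aggregate_responsible_regions",
    "quantify_overlap",
]

_REGION_LABELS = {"NET": 1, "ED": 2, "ET": 3}


@dataclass
class BackgroundVector:
    """Modal codeword over background latent positions."""

    index: int
    support_fraction: float


def _background_latent_mask(foreground: np.ndarray, reduction: int) -> np.ndarray:
    """Map per-pixel background to latent resolution by strict majority.

    ``foreground`` is (I, W, H) boolean; a latent cell counts as background
    when more than half of its reduction x reduction footprint is
    background.
    """
    i, w, h = foreground.shape
    r = reduction
    frac_bg = (~foreground).reshape(i, w // r, r, h // r, r).mean(axis=(2, 4))
    return frac_bg > 0.5


def _background_occupancy(volumes, net: VQSegNet, target_size=None):
    """Per-codeword occurrence counts at background vs all latent positions."""
    bg_counts = np.zeros(net.codebook.K, dtype=np.int64)
    all_counts = np.zeros(net.codebook.K, dtype=np.int64)
    total_bg = 0
    for v in volumes:
        pre = v if isinstance(v, PreprocessedVolume) else preprocess_volume(v, target_size)
        q = net.quantize(net.encode(pre.images), count_usage=False)
        bg = _background_latent_mask(pre.foreground, net.config.reduction)
        bg_counts += np.bincount(q.indices[bg], minlength=net.codebook.K)
        all_counts += np.bincount(q.indices.ravel(), minlength=net.codebook.K)
        total_bg += int(bg.sum())
    return bg_counts, all_counts, total_bg


def find_background_vector(volumes, net: VQSegNet, target_size=None) -> BackgroundVector:
    """Identify the most common codeword over background latent positions."""
    bg_counts, _, total_bg = _background_occupancy(volumes, net, target_size)
    if total_bg == 0:
        raise ValueError("no background latent positions found")
    best = int(np.argmax(bg_counts))  # lowest index wins ties
    return BackgroundVector(index=best,
                            support_fraction=float(bg_counts[best] / total_bg))


def background_codewords(volumes, net: VQSegNet, threshold: float = 0.5,
                         target_size=None) -> list[int]:
    """Codewords that predominantly encode background.

    Returns every codeword whose occurrences lie at background latent
    positions more often than ``threshold``. Such codewords describe the
    region outside the body, not an imaging phenotype, so downstream
    analyses exclude them from responsible-vector candidacy (the modal one
    doubles as the replacement vector for ablation).
    """
    bg_counts, all_counts, total_bg = _background_occupancy(volumes, net, target_size)
    if total_bg == 0:
        raise ValueError("no background latent positions found")
    with np.errstate(invalid="ignore"):
        frac = np.where(all_counts > 0, bg_counts / np.maximum(all_counts, 1), 0.0)
    return [int(k) for k in np.flatnonzero(frac > threshold)]


@dataclass
class ResponsibleRegionMap:
    """Per-pixel L1 logit difference caused by ablating codeword(s)."""

    values: np.ndarray  # W x H (single slice) or I x W x H (volume stack)
    ablated: tuple[int, ...]
    normalization: str = "raw"  # {"raw", "per-patient-standardized"}

    def standardized(self) -> "ResponsibleRegionMap":
        """Z-score the map values for display (as in per-patient figures)."""
        v = self.values
        sd = v.std()
        out = (v - v.mean()) / (sd if sd > 0 else 1.0)
        return ResponsibleRegionMap(values=out, ablated=self.ablated,
                                    normalization="per-patient-standardized")


def _replace(indices: np.ndarray, target: int, background: int,
             net: VQSegNet) -> np.ndarray:
    idx2 = np.where(indices == target, background, indices)
    vec = net.codebook.vectors[idx2]  # (..., D)
    return np.moveaxis(vec, -1, -3)


def ablate_codeword(quantized: QuantizedLatent, target: int,
                    background: BackgroundVector | int,
                    net: VQSegNet, frozen_norm: bool = True) -> ResponsibleRegionMap:
    """Responsible-region map of one codeword for one quantized latent grid.

    With ``frozen_norm`` (default) the replaced latent is decoded under the
    normalization statistics captured from the original decode, so the
    difference map isolates the causal local effect of the replacement
    rather than shifts of slice-level statistics.
    """
    bg_idx = background.index if isinstance(background, BackgroundVector) else int(background)
    if not 0 <= target < net.codebook.K:
        raise ValueError(f"target codeword {target} outside [0, {net.codebook.K})")
    if target == bg_idx:
        warnings.warn("ablating the background vector itself yields a zero map",
                      RuntimeWarning, stacklevel=2)
    net.clear_decoder_stats()
    if frozen_norm:
        with net.capture_decoder_stats():
            logits = net.decode(quantized.values).logits
    else:
        logits = net.decode(quantized.values).logits
    values2 = _replace(quantized.indices, target, bg_idx, net)
    logits2 = net.decode(values2).logits
    net.clear_decoder_stats()
    axis = 0 if quantized.values.ndim == 3 else 1
    diff = np.abs(logits - logits2).sum(axis=axis)
    return ResponsibleRegionMap(values=diff, ablated=(target,))


def aggregate_responsible_regions(volumes, net: VQSegNet, codewords: list[int],
                                  background: BackgroundVector | int,
                                  target_size=None,
                                  frozen_norm: bool = True) -> list[ResponsibleRegionMap]:
    """Per-volume maps: sum of one-at-a-time ablation maps over a codeword set.

    Returns one I x W x H raw map stack per volume (slice axis first).
    """
    if not codewords:
        raise ValueError("empty codeword set")
    bg_idx = background.index if isinstance(background, BackgroundVector) else int(background)
    out = []
    for v in volumes:
        pre = v if isinstance(v, PreprocessedVolume) else preprocess_volume(v, target_size)
        q = net.quantize(net.encode(pre.images), count_usage=False)
        net.clear_decoder_stats()
        if frozen_norm:
            with net.capture_decoder_stats():
                base = net.decode(q.values).logits
        else:
            base = net.decode(q.values).logits
        acc = np.zeros(base.shape[:1] + base.shape[2:], dtype=np.float64)
        for k in codewords:
            if not np.any(q.indices == k):
                continue  # absent codeword: exactly zero contribution
            logits2 = net.decode(_replace(q.indices, k, bg_idx, net)).logits
            acc += np.abs(base - logits2).sum(axis=1)
        net.clear_decoder_stats()
        out.append(ResponsibleRegionMap(values=acc, ablated=tuple(codewords)))
    return out


@dataclass
class RegionOverlapStats:
    """Per-label responsible-region mass and its nonparametric comparison."""

    sums: pd.DataFrame  # one row per volume: volume_id, NET, ED, ET, flags
    kruskal_statistic: float
    kruskal_p: float
    dunn: DunnResult
    shapiro_p: dict[str, float]
    medians: dict[str, float]

    @property
    def highest_median_label(self) -> str:
        return max(self.medians, key=self.medians.get)


def quantify_overlap(maps: list[ResponsibleRegionMap], volumes,
                     alpha_gate: float = 0.05) -> RegionOverlapStats:
    """Sum raw map values within each ground-truth label and compare labels.

    ``maps[i].values`` must be an I x W x H stack aligned with
    ``volumes[i]`` (labels at the same resolution). A label absent from a
    volume contributes a flagged zero sum.
    """
    rows = []
    for m, v in zip(maps, volumes):
        labels = v.labels if isinstance(v, (LabeledVolume, PreprocessedVolume)) else v
        if isinstance(v, LabeledVolume):
            labels = np.moveaxis(v.labels, -1, 0)  # to I x W x H
        elif isinstance(v, PreprocessedVolume):
            labels = v.labels
        if m.normalization != "raw":
            raise ValueError("overlap statistics require raw (unstandardized) maps")
        if m.values.shape != labels.shape:
            raise ValueError("map and label shapes differ")
        row = {"volume_id": getattr(v, "volume_id", "")}
        for name, lab in _REGION_LABELS.items():
            mask = labels == lab
            row[name] = float(m.values[mask].sum()) if mask.any() else 0.0
            row[f"{name}_absent"] = not bool(mask.any())
        rows.append(row)
    sums = pd.DataFrame(rows)
    groups = {name: sums[name].to_numpy() for name in _REGION_LABELS}
    shapiro_p = {}
    for name, arr in groups.items():
        try:
            shapiro_p[name] = float(sps.shapiro(arr).pvalue) if arr.size >= 3 else np.nan
        except Exception:
            shapiro_p[name] = np.nan
    kw = sps.kruskal(*groups.values())
    dunn = dunn_test(groups)
    return RegionOverlapStats(
        sums=sums,
        kruskal_statistic=float(kw.statistic),
        kruskal_p=float(kw.pvalue),
        dunn=dunn,
        shapiro_p=shapiro_p,
        medians={k: float(np.median(a)) for k, a in groups.items()},
    )
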