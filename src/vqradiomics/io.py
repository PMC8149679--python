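"""NIfTI volume I/O, manifests and run configuration.

Volumes follow the skull-stripped multi-parametric MR layout: one NIfTI
file per channel plus one label file, all sharing geometry. A manifest CSV
lists, per volume: ``volume_id``, ``grade`` (LGG/HGG/unknown) and the file
paths. Affines are passed through untouched; voxel indices are 0-based
with the axial slice axis last (C x W x H x I).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .phantom import LabeledVolume

__all__ = [
    "GRADE_NAMES",
    "write_volume",
    "read_volume",
    "write_manifest",
    "read_manifest",
    "load_volumes",
    "save_run_config",
    "load_run_config",
]

GRADE_NAMES = {0: "LGG", 1: "HGG", None: "unknown"}
_GRADE_CODES = {"LGG": 0, "HGG": 1, "unknown": None}


def write_volume(volume: LabeledVolume, out_dir, affine: np.ndarray | None = None
                 ) -> dict:
    """Write one volume as per-channel NIfTI files plus a label file.

    Returns the manifest row (volume_id, grade, channel paths, label path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = np.eye(4) if affine is None else affine
    channel_paths = []
    for c in range(volume.image.shape[0]):
        p = out_dir / f"{volume.volume_id}_ch{c}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(volume.image[c], dtype=np.float32), aff), p)
        channel_paths.append(str(p))
    label_path = ""
    if volume.labels is not None:
        p = out_dir / f"{volume.volume_id}_seg.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(volume.labels, dtype=np.int16), aff), p)
        label_path = str(p)
    return {
        "volume_id": volume.volume_id,
        "grade": GRADE_NAMES[volume.grade],
        "channels": ";".join(channel_paths),
        "labels": label_path,
    }


def read_volume(row: dict, n_labels: int = 4) -> LabeledVolume:
    """Load one manifest row; channels stacked in manifest order."""
    channel_paths = [p for p in str(row["channels"]).split(";") if p]
    if not channel_paths:
        raise ValueError(f"volume {row.get('volume_id')}: no channel files listed")
    imgs = []
    shapes = {}
    for p in channel_paths:
        img = nib.load(p)
        data = np.asarray(img.dataobj, dtype=np.float32)
        imgs.append(data)
        shapes[p] = data.shape
    if len({s for s in shapes.values()}) != 1:
        detail = ", ".join(f"{Path(p).name}: {s}" for p, s in shapes.items())
        raise ValueError(f"channel geometry mismatch ({detail})")
    image = np.stack(imgs)
    labels = None
    label_path = str(row.get("labels", "") or "")
    if label_path:
        labels = np.asarray(nib.load(label_path).dataobj).astype(np.int16)
        if labels.shape != image.shape[1:]:
            raise ValueError("label geometry differs from channels")
        if labels.min() < 0 or labels.max() >= n_labels:
            raise ValueError(
                f"label values outside [0, {n_labels}) in {label_path}")
    grade = row.get("grade", "unknown")
    grade = _GRADE_CODES[grade] if isinstance(grade, str) else grade
    return LabeledVolume(image=image, labels=labels, grade=grade,
                         volume_id=str(row["volume_id"]))


def write_manifest(rows: list[dict], path) -> None:
    df = pd.DataFrame(rows)
    if df["volume_id"].duplicated().any():
        raise ValueError("duplicate volume ids in manifest")
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    required = {"volume_id", "grade", "channels"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["volume_id"].duplicated().any():
        raise ValueError("duplicate volume ids in manifest")
    return df


def load_volumes(manifest_path, n_labels: int = 4) -> list[LabeledVolume]:
    df = read_manifest(manifest_path)
    return [read_volume(row, n_labels=n_labels) for row in df.to_dict("records")]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_run_config(config: dict, path) -> None:
    """Serialize a (possibly nested, dataclass-bearing) run config as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def load_run_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def model_to_json(model, path) -> None:
    """Persist a fitted grade model (coefficients, scaling, metadata)."""
    payload = {
        "intercept": model.intercept,
        "coefficients": model.coefficients.tolist(),
        "feature_subset": model.feature_subset.tolist(),
        "regularization": model.regularization,
        "l2_lambda": model.l2_lambda,
        "feature_means": model.feature_means.tolist(),
        "feature_stds": model.feature_stds.tolist(),
        "objective": model.objective,
        "n_samples": model.n_samples,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
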