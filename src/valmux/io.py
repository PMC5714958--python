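"""File-format plumbing: NIfTI volumes, trial tables, ground-truth sidecars."""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np
import pandas as pd

from .config import StudyConfig
from .synth import GroundTruth

__all__ = [
    "save_volume",
    "load_volume",
    "save_trials",
    "load_trials",
    "save_ground_truth",
    "load_ground_truth",
]


def save_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3-D or 4-D volume as NIfTI-1 (float32 data, exact affine)."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_volume(path, expected_affine: np.ndarray | None = None):
    """Read a NIfTI volume; optionally enforce the study affine exactly."""
    img = nib.load(str(path))
    affine = img.affine
    if expected_affine is not None and not np.allclose(affine, expected_affine):
        raise ValueError(
            f"affine mismatch: file {affine.tolist()} vs expected "
            f"{np.asarray(expected_affine).tolist()}"
        )
    return np.asarray(img.get_fdata()), affine


def save_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def load_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_ground_truth(truth: GroundTruth, config: StudyConfig, stem) -> None:
    """Ground truth as NIfTI effect maps plus a JSON sidecar."""
    aff = config.affine()
    save_volume(truth.value_slope, aff, f"{stem}_value_slope.nii.gz")
    save_volume(truth.saliency_coef, aff, f"{stem}_saliency_coef.nii.gz")
    save_volume(truth.mean_offset, aff, f"{stem}_mean_offset.nii.gz")
    for cat, pat in truth.category_patterns.items():
        save_volume(pat, aff, f"{stem}_pattern_{cat}.nii.gz")
    meta = {
        "noise_seed_entropy": truth.noise_seed_entropy,
        "categories_with_patterns": sorted(truth.category_patterns),
    }
    with open(f"{stem}_truth.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_ground_truth(config: StudyConfig, stem) -> GroundTruth:
    aff = config.affine()
    with open(f"{stem}_truth.json") as fh:
        meta = json.load(fh)
    value, _ = load_volume(f"{stem}_value_slope.nii.gz", aff)
    sal, _ = load_volume(f"{stem}_saliency_coef.nii.gz", aff)
    mean, _ = load_volume(f"{stem}_mean_offset.nii.gz", aff)
    pats = {}
    for cat in meta["categories_with_patterns"]:
        pats[cat], _ = load_volume(f"{stem}_pattern_{cat}.nii.gz", aff)
    return GroundTruth(value, sal, mean, pats, meta["noise_seed_entropy"])
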