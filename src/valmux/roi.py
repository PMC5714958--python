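"""Region-of-interest analyses: LOSO definition, mask stats, rating profiles.

The leave-one-subject-out (LOSO) procedure defines each subject's ROI from
the other n-1 subjects only: their group t-map is cluster-FWE thresholded,
the surviving cluster best overlapping a target seed mask is selected, and a
sphere of fixed radius around its center of gravity becomes the held-out
subject's ROI.  This keeps ROI selection independent of the data later
analysed inside it (no double-dipping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .config import sphere_roi

__all__ = [
    "loso_define",
    "extract_roi_betas",
    "roi_effect_tests",
    "rating_profile",
    "LosoResult",
]


@dataclass
class LosoResult:
    """Per-fold ROI masks (None where no interim cluster survived)."""

    masks: list[np.ndarray | None]
    centers: list[np.ndarray | None]
    undefined_folds: list[int]

    @property
    def n_defined(self) -> int:
        return sum(m is not None for m in self.masks)


def _fold_roi(
    fold_betas: np.ndarray,
    seed_mask: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm,
    radius_mm: float,
    voxel_p: float,
    alpha: float,
    n_sims: int,
    rng: np.random.Generator,
):
    t_map, df = glm.group_ttest(fold_betas, mask)
    resid = fold_betas - np.nanmean(fold_betas, axis=0)
    fwhm = glm.estimate_smoothness(np.moveaxis(resid, 0, -1), mask, voxel_size_mm)
    k = glm.cluster_threshold(
        t_map.shape, mask, fwhm, voxel_size_mm, voxel_p, alpha, n_sims, rng
    )
    t_crit = stats.t.isf(voxel_p / 2.0, df)
    clusters, _ = glm.apply_threshold(t_map, t_crit, k)
    best, best_overlap = None, 0
    for cl in clusters:
        cl_mask = np.zeros(mask.shape, dtype=bool)
        cl_mask[tuple(cl.voxels.T)] = True
        overlap = int((cl_mask & seed_mask).sum())
        if overlap > best_overlap:
            best, best_overlap = cl, overlap
    if best is None:
        return None, None
    center = best.center_of_gravity
    sphere = sphere_roi(mask.shape, voxel_size_mm, center, radius_mm)
    sphere &= mask
    if not sphere.any():
        return None, None
    return sphere, center


def loso_define(
    contrast_betas: np.ndarray,
    seed_mask: np.ndarray,
    voxel_size_mm,
    radius_mm: float = 5.0,
    mask: np.ndarray | None = None,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    n_sims: int = 1000,
    rng: np.random.Generator | None = None,
) -> LosoResult:
    """Leave-one-subject-out spherical ROIs around interim-cluster centers.

    ``contrast_betas``: (n_subjects, *grid) single-subject contrast volumes.
    For each held-out subject, the remaining n-1 subjects' maps are
    thresholded (per-voxel ``voxel_p``, cluster FWE ``alpha`` with
    ``n_sims`` simulated fields); the surviving cluster with maximal overlap
    with ``seed_mask`` is chosen and a sphere of ``radius_mm`` at its
    (unweighted) center of gravity becomes the fold's ROI.  Folds with no
    surviving overlapping cluster are reported undefined.
    """
    contrast_betas = np.asarray(contrast_betas, dtype=float)
    n = contrast_betas.shape[0]
    if n < 4:
        raise ValueError("LOSO needs at least 4 subjects")
    if mask is None:
        mask = ~np.isnan(contrast_betas).any(axis=0)
    rng = np.random.default_rng() if rng is None else rng
    masks: list[np.ndarray | None] = []
    centers: list[np.ndarray | None] = []
    undefined = []
    for held_out in range(n):
        others = np.delete(contrast_betas, held_out, axis=0)
        sphere, center = _fold_roi(
            others, seed_mask, mask, voxel_size_mm, radius_mm,
            voxel_p, alpha, n_sims, rng,
        )
        masks.append(sphere)
        centers.append(center)
        if sphere is None:
            undefined.append(held_out)
    return LosoResult(masks, centers, undefined)


def extract_roi_betas(beta_volume: np.ndarray, roi: np.ndarray) -> float:
    """Mean beta over in-mask voxels (NaN voxels excluded)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI mask is empty")
    return float(np.nanmean(np.asarray(beta_volume, dtype=float)[roi]))


def roi_effect_tests(
    value_betas: np.ndarray, saliency_betas: np.ndarray
) -> pd.DataFrame:
    """One-sample t tests of the per-subject ROI value and saliency betas.

    Both regressors come from the joint value + saliency GLM; subjects with
    NaN (undefined ROI) are dropped per effect.
    """
    rows = []
    for name, vals in (("value", value_betas), ("saliency", saliency_betas)):
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) < 3:
            raise ValueError(f"{name}: fewer than 3 subjects with a defined ROI")
        res = stats.ttest_1samp(v, 0.0)
        rows.append(
            {"effect": name, "mean_beta": v.mean(), "t": float(res.statistic),
             "p": float(res.pvalue), "df": len(v) - 1, "n": len(v)}
        )
    return pd.DataFrame(rows)


def rating_profile(level_betas: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Rating-binned ROI activation profile and mixed-effects slope test.

    ``level_betas``: long table with columns ``subject_id``, ``level``
    (pleasantness rating 1-9) and ``beta`` (mean ROI beta from the
    nine-rating-level GLM); levels absent for a subject are simply missing
    rows.  Returns the per-level mean +/- SEM profile and the slope of a
    mixed-effects regression of beta on rating level with a subject random
    intercept.
    """
    import statsmodels.formula.api as smf

    df = level_betas.dropna(subset=["beta"]).copy()
    prof = (
        df.groupby("level")["beta"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    md = smf.mixedlm("beta ~ level", df, groups=df["subject_id"])
    try:
        fit = md.fit(reml=True, method="lbfgs")
        slope = {
            "slope": float(fit.params["level"]),
            "z": float(fit.tvalues["level"]),
            "p": float(fit.pvalues["level"]),
            "fallback_ols": False,
        }
    except Exception:
        # singular random-effects fit: subject-demeaned fixed-effects slope
        d = df.copy()
        d["beta_c"] = d["beta"] - d.groupby("subject_id")["beta"].transform("mean")
        d["level_c"] = d["level"] - d.groupby("subject_id")["level"].transform("mean")
        res = stats.linregress(d["level_c"], d["beta_c"])
        slope = {
            "slope": float(res.slope),
            "z": float(res.slope / res.stderr) if res.stderr else np.nan,
            "p": float(res.pvalue),
            "fallback_ols": True,
        }
    return prof, slope
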