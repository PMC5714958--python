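"""Canonical synthetic study conditions.

These configurations define the cohorts on which the pipeline is validated:
sample sizes mirror the emulated study (18 subjects behaviourally, 17 for
pattern analyses after the one exclusion, 12 for the reduced univariate
cohort), the paradigm is the 4-category x 4-level design with 96 trials,
and signal amplitudes are fixed here once, calibrated so that the injected
univariate effects reach a single-subject voxel t of about 3 (a realistic
effect size for slow event-related designs).  Tests and validation scripts
import these functions rather than re-tuning parameters locally.
"""

from __future__ import annotations

import numpy as np

from .config import EffectSpec, NoiseSpec, StudyConfig, box_roi

__all__ = [
    "ROI_A",
    "ROI_B",
    "ROI_C",
    "behavior_config",
    "univariate_recovery_config",
    "null_betas_config",
    "rsa_category_config",
    "rsa_rank1_value_config",
    "rsa_null_config",
    "pca_roi_config",
    "demo_config",
]

#: single-subject voxelwise t target for injected univariate effects
# amplitude per rating point such that the value-modulator t is ~3 at the
# default noise level (see docs/methods.md for the calibration procedure)
VALUE_AMPLITUDE = 0.04
SALIENCY_AMPLITUDE = 0.02
#: multi-voxel category pattern norm, in noise-SD units across the ROI
PATTERN_AMPLITUDE = 9.0


def ROI_A(grid_shape=(24, 24, 24)) -> np.ndarray:
    """5x5x5 box in one octant of the grid (univariate value site)."""
    return box_roi(grid_shape, (4, 4, 4), (8, 8, 8))


def ROI_B(grid_shape=(24, 24, 24)) -> np.ndarray:
    """5x5x5 box in the opposite octant (univariate saliency site)."""
    hi = np.asarray(grid_shape) - 5
    return box_roi(grid_shape, hi - 4, hi)


def ROI_C(grid_shape=(20, 20, 20)) -> np.ndarray:
    """6x6x6 central box (multi-voxel category-pattern site)."""
    c = np.asarray(grid_shape) // 2
    return box_roi(grid_shape, c - 3, c + 2)


def behavior_config(seed: int = 0, n_subjects: int = 18, null: bool = False) -> StudyConfig:
    """Rating generator with opposing reward/punishment level slopes.

    ``null=True`` zeroes all slopes for calibration checks of the ANOVA.
    """
    slopes = (
        {c: 0.0 for c in ("gain", "loss", "face", "shock")}
        if null
        else {"gain": 1.0, "loss": -1.0, "face": 1.0, "shock": -1.0}
    )
    return StudyConfig(
        n_subjects=n_subjects,
        grid_shape=(4, 4, 4),
        seed=seed,
        rating_slopes=slopes,
    )


def univariate_recovery_config(
    seed: int = 0, n_subjects: int = 12, grid: int = 24
) -> StudyConfig:
    """Value effect in ROI-A, saliency effect in ROI-B, full time series."""
    shape = (grid, grid, grid)
    return StudyConfig(
        n_subjects=n_subjects,
        grid_shape=shape,
        seed=seed,
        noise=NoiseSpec(sigma=1.0, ar1_rho=0.3, smooth_fwhm_mm=4.0),
        effects=[
            EffectSpec("value_linear", ROI_A(shape), VALUE_AMPLITUDE),
            EffectSpec("saliency_quadratic", ROI_B(shape), SALIENCY_AMPLITUDE),
        ],
    )


def null_betas_config(seed: int = 0, n_subjects: int = 12, grid: int = 24) -> StudyConfig:
    """No injected effects; used for family-wise error calibration."""
    return StudyConfig(
        n_subjects=n_subjects,
        grid_shape=(grid, grid, grid),
        seed=seed,
        noise=NoiseSpec(sigma=1.0, ar1_rho=0.3, smooth_fwhm_mm=4.0),
    )


def rsa_category_config(seed: int = 0, n_subjects: int = 17, grid: int = 20) -> StudyConfig:
    """Zero-mean category patterns in ROI-C; no univariate effect there."""
    shape = (grid, grid, grid)
    return StudyConfig(
        n_subjects=n_subjects,
        grid_shape=shape,
        seed=seed,
        noise=NoiseSpec(sigma=1.0, ar1_rho=0.3, smooth_fwhm_mm=3.0),
        effects=[EffectSpec("category_pattern", ROI_C(shape), PATTERN_AMPLITUDE)],
    )


def rsa_rank1_value_config(seed: int = 0, n_subjects: int = 17, grid: int = 20) -> StudyConfig:
    """Rank-1 value signal: a common spatial profile scaled by condition value.

    The profile covers the whole analysis volume, so every searchlight sees
    the same pattern under positive scaling — the regime in which Pearson
    correlational distance is provably blind to the signal while univariate
    value mapping sees it everywhere.  (At the edge of a bounded profile the
    spatial gradient itself becomes a pattern and pattern analyses can pick
    it up; see the methods note.)
    """
    shape = (grid, grid, grid)
    whole = np.ones(shape, dtype=bool)
    return StudyConfig(
        n_subjects=n_subjects,
        grid_shape=shape,
        seed=seed,
        noise=NoiseSpec(sigma=1.0, ar1_rho=0.3, smooth_fwhm_mm=3.0),
        effects=[EffectSpec("value_linear", whole, 0.25)],
    )


def rsa_null_config(seed: int = 0, n_subjects: int = 17, grid: int = 20) -> StudyConfig:
    """Pure-noise condition betas for searchlight null calibration."""
    return StudyConfig(
        n_subjects=n_subjects,
        grid_shape=(grid, grid, grid),
        seed=seed,
        noise=NoiseSpec(sigma=1.0, ar1_rho=0.0, smooth_fwhm_mm=0.0),
    )


def pca_roi_config(
    seed: int = 0,
    n_subjects: int = 17,
    grid: int = 12,
    value_amplitude: float = 1.0,
    pattern_amplitude: float = 18.0,
) -> StudyConfig:
    """Uniform value signal plus zero-mean category patterns in one ROI.

    The multiplexing scenario: a mean-activity value code (PC1) coexisting
    with a multi-voxel category code (later PCs) in the same region.  The
    category patterns are group-shared (a consistent population code, the
    regime in which group-level fixed-effect category tests are meaningful),
    zero-mean over the ROI (hence orthogonal to the uniform value direction
    in voxel space), and their condition weights are residualized against
    condition value (hence decorrelated from the value code at the
    condition level too — without this the two codes are inherently
    entangled, since rewards are rated high).  Amplitudes are set so that
    the value component's eigenvalue clears the category components', which
    in turn clear the random-matrix noise edge of a 16 x m Gaussian matrix
    (see docs/methods.md).
    """
    shape = (grid, grid, grid)
    roi = box_roi(shape, (3, 3, 3), (8, 8, 8))
    effects = []
    if value_amplitude:
        effects.append(EffectSpec("value_linear", roi, value_amplitude))
    if pattern_amplitude:
        effects.append(
            EffectSpec(
                "category_pattern",
                roi,
                pattern_amplitude,
                shared_pattern=True,
                orthogonalize_to_value=True,
            )
        )
    return StudyConfig(
        n_subjects=n_subjects,
        grid_shape=shape,
        seed=seed,
        noise=NoiseSpec(sigma=1.0, ar1_rho=0.0, smooth_fwhm_mm=0.0),
        effects=effects,
    )


def demo_config(seed: int = 0, n_subjects: int = 12, grid: int = 20) -> StudyConfig:
    """Small end-to-end demonstration cohort for the pipeline."""
    shape = (grid, grid, grid)
    return StudyConfig(
        n_subjects=n_subjects,
        grid_shape=shape,
        seed=seed,
        noise=NoiseSpec(sigma=1.0, ar1_rho=0.3, smooth_fwhm_mm=3.0),
        effects=[
            EffectSpec("value_linear", box_roi(shape, (3, 3, 3), (7, 7, 7)), VALUE_AMPLITUDE * 1.5),
            EffectSpec(
                "saliency_quadratic",
                box_roi(shape, (12, 12, 12), (16, 16, 16)),
                SALIENCY_AMPLITUDE * 1.5,
            ),
            EffectSpec("category_pattern", ROI_C(shape), PATTERN_AMPLITUDE),
        ],
    )
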