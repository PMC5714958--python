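"""Synthetic cohort generator with known injected value/saliency/category structure.

Every downstream stage (behavioral ANOVA, univariate GLM, LOSO ROI, searchlight
RSA, ROI PCA) is exercised against cohorts produced here, so the generator
doubles as the test oracle: it records, per subject, exactly which voxels carry
which signal and at what amplitude (:class:`GroundTruth`).

Two output pathways exist:

* :func:`generate_bold` — a full forward model producing 4-D voxel time
  series: HRF-convolved cue-period signals plus AR(1), spatially smoothed
  Gaussian noise.  Inter-trial intervals carry noise only (baseline).
* :func:`generate_condition_betas` — condition-level beta volumes emitted
  directly (the 16-condition GLM's expected output plus beta noise), which
  decouples pattern-analysis tests from GLM runtime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .config import (
    CATEGORIES,
    CONDITIONS,
    LEVELS,
    NEUTRAL_RATING,
    EffectSpec,
    StudyConfig,
)
from .glm import convolve_events

__all__ = [
    "GroundTruth",
    "generate_trial_schedule",
    "generate_ratings",
    "make_ground_truth",
    "generate_bold",
    "generate_condition_betas",
    "generate_cohort",
    "generate_beta_cohort",
]


@dataclass
class GroundTruth:
    """Per-subject record of injected effects; consumed only by tests/validation."""

    value_slope: np.ndarray  # 3-D, signal units per rating point
    saliency_coef: np.ndarray  # 3-D, signal units per squared-deviation point
    mean_offset: np.ndarray  # 3-D, signal units
    category_patterns: dict[str, np.ndarray] = field(default_factory=dict)  # 3-D each
    noise_seed_entropy: int = 0
    #: residualize category-pattern condition weights against condition value
    ortho_category_to_value: bool = False

    def rois(self) -> dict[str, np.ndarray]:
        out = {
            "value": self.value_slope != 0,
            "saliency": self.saliency_coef != 0,
            "mean": self.mean_offset != 0,
        }
        if self.category_patterns:
            cat = np.zeros_like(self.value_slope, dtype=bool)
            for pat in self.category_patterns.values():
                cat |= pat != 0
            out["category"] = cat
        return out


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Trial schedule and ratings


def generate_trial_schedule(config: StudyConfig, subject_seed) -> pd.DataFrame:
    """Balanced, randomized trial schedule for one subject.

    Each of the 16 (category, level) cells appears ``n_trials / 16`` times;
    ``round(actualized_fraction * reps)`` trials per cell are actualized.
    ITIs are drawn uniformly from ``iti_range_s`` and snapped to the TR grid,
    so with the default 2 s TR the jitter takes values 10 or 12 s.
    """
    config.validate()
    rng = _rng(subject_seed)
    reps = config.reps_per_condition
    n_act = int(round(config.actualized_fraction * reps))

    rows = []
    for cat, lvl in CONDITIONS:
        actual = np.zeros(reps, dtype=bool)
        actual[rng.choice(reps, size=n_act, replace=False)] = True
        for a in actual:
            rows.append((cat, lvl, bool(a)))
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    itis = rng.uniform(*config.iti_range_s, size=len(rows))
    itis = np.round(itis / config.tr_s) * config.tr_s

    t = config.lead_in_s
    records = []
    for i, ((cat, lvl, act), iti) in enumerate(zip(rows, itis)):
        records.append(
            {
                "block": i // config.trials_per_block,
                "trial_index": i,
                "category": cat,
                "level": lvl,
                "actualized": act,
                "cue_onset_s": t,
                "outcome_onset_s": t + config.trial_length_s / 2.0,
            }
        )
        t += config.trial_length_s + iti
    return pd.DataFrame.from_records(records)


def generate_ratings(
    config: StudyConfig, subject_seed, trials: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Fill pleasantness ratings (1-9) with opposing magnitude trends.

    Latent rating = 5 + slope(category) * level + subject intercept + noise,
    rounded to the nearest integer and clipped to the 1-9 scale, so the
    expected rating increases with level for rewards (positive slopes) and
    decreases for punishments (negative slopes); the neutral point 5 is
    recovered exactly at zero effect.  A fraction ``missing_rate`` of trials
    is marked missed (rating NaN).
    """
    if trials is None:
        trials = generate_trial_schedule(config, subject_seed)
    trials = trials.copy()
    # independent substream so the schedule is unchanged by rating parameters
    rng = _rng(np.random.SeedSequence(entropy=_entropy_of(subject_seed), spawn_key=(1,)))
    intercept = rng.normal(0.0, config.rating_subject_sd)
    slopes = trials["category"].map(config.rating_slopes).to_numpy(dtype=float)
    latent = (
        NEUTRAL_RATING
        + slopes * trials["level"].to_numpy(dtype=float)
        + intercept
        + rng.normal(0.0, config.rating_noise_sd, size=len(trials))
    )
    rating = np.clip(np.rint(latent), 1, 9)
    if config.missing_rate > 0:
        missed = rng.random(len(trials)) < config.missing_rate
        rating = np.where(missed, np.nan, rating)
    trials["rating"] = rating
    return trials


def _entropy_of(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        ent = seed.entropy
        key = seed.spawn_key
        # fold the spawn key into a single integer entropy
        val = int(ent) if not isinstance(ent, (list, tuple)) else int(ent[0])
        for k in key:
            val = val * 1000003 + int(k) + 1
        return val % (2**63)
    return int(seed)


# ---------------------------------------------------------------------------
# Ground truth construction


def make_ground_truth(config: StudyConfig, subject_seed) -> GroundTruth:
    """Materialize the per-subject effect maps declared in ``config.effects``.

    Category patterns are drawn once per subject per ROI as zero-mean,
    unit-norm vectors over the ROI voxels: they are invisible to the ROI
    mean, isolating the multi-voxel (RSA/PCA) pathway from univariate
    analyses.
    """
    shape = config.grid_shape
    gt = GroundTruth(
        value_slope=np.zeros(shape),
        saliency_coef=np.zeros(shape),
        mean_offset=np.zeros(shape),
        noise_seed_entropy=_entropy_of(subject_seed),
    )
    for eff in config.effects:
        if eff.kind == "value_linear":
            gt.value_slope[eff.roi] += eff.amplitude
        elif eff.kind == "saliency_quadratic":
            gt.saliency_coef[eff.roi] += eff.amplitude
        elif eff.kind == "mean_offset":
            gt.mean_offset[eff.roi] += eff.amplitude
        elif eff.kind == "category_pattern":
            entropy = (
                int(eff.pattern_seed) + 1
                if eff.shared_pattern
                else _entropy_of(subject_seed)
            )
            prng = _rng(
                np.random.SeedSequence(entropy=entropy, spawn_key=(2, int(eff.pattern_seed)))
            )
            m = int(eff.roi.sum())
            for cat in CATEGORIES:
                vec = prng.normal(size=m)
                vec -= vec.mean()
                vec /= np.linalg.norm(vec)
                pat = gt.category_patterns.setdefault(cat, np.zeros(shape))
                pat[eff.roi] += eff.amplitude * vec
            if eff.orthogonalize_to_value:
                gt.ortho_category_to_value = True
    return gt


def category_condition_weights(
    trials: pd.DataFrame, orthogonalize_to_value: bool
) -> pd.DataFrame:
    """Per-condition weight of each category's pattern (16 x 4 table).

    Plain category indicators by default; with ``orthogonalize_to_value``
    each indicator column is residualized against {1, condition mean rating}
    across the 16 conditions, so the injected category code carries no
    condition-level value component.
    """
    mods = condition_modulators(trials)
    idx = pd.MultiIndex.from_tuples(CONDITIONS, names=["category", "level"])
    w = pd.DataFrame(
        {cat: [float(c == cat) for c, _ in CONDITIONS] for cat in CATEGORIES},
        index=idx,
    )
    if orthogonalize_to_value:
        r = mods["rating"].to_numpy(dtype=float)
        x = np.column_stack([np.ones(16), r])
        proj = x @ np.linalg.pinv(x)
        for cat in CATEGORIES:
            w[cat] = w[cat].to_numpy() - proj @ w[cat].to_numpy()
    return w


# ---------------------------------------------------------------------------
# Noise


def make_noise(
    config: StudyConfig, n_scans: int, rng: np.random.Generator
) -> np.ndarray:
    """AR(1), spatially smoothed Gaussian noise, rescaled to marginal SD sigma.

    Returns an array of shape ``(*grid_shape, n_scans)``.
    """
    spec = config.noise
    shape = config.grid_shape
    burn = 20 if spec.ar1_rho > 0 else 0
    eps = rng.standard_normal(size=(*shape, n_scans + burn))
    if spec.ar1_rho > 0:
        eps = lfilter([1.0], [1.0, -spec.ar1_rho], eps, axis=-1)
    eps = eps[..., burn:]
    if spec.smooth_fwhm_mm > 0:
        sigmas = [
            spec.smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
            for vs in config.voxel_size_mm
        ]
        eps = gaussian_filter(eps, sigma=sigmas + [0.0])
    sd = eps.std()
    if sd > 0:
        eps *= spec.sigma / sd
    return eps


def _smooth_noise_volume(
    config: StudyConfig, rng: np.random.Generator, n_vols: int
) -> np.ndarray:
    """Spatially smoothed (no temporal structure) noise volumes, SD sigma."""
    spec = config.noise
    eps = rng.standard_normal(size=(n_vols, *config.grid_shape))
    if spec.smooth_fwhm_mm > 0:
        sigmas = [
            spec.smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
            for vs in config.voxel_size_mm
        ]
        eps = gaussian_filter(eps, sigma=[0.0] + sigmas)
    sd = eps.std()
    if sd > 0:
        eps *= spec.sigma / sd
    return eps


# ---------------------------------------------------------------------------
# Forward models


def n_scans_for(config: StudyConfig, trials: pd.DataFrame) -> int:
    duration = trials["cue_onset_s"].iloc[-1] + config.trial_length_s + config.tail_s
    return int(np.ceil(duration / config.tr_s))


def generate_bold(
    config: StudyConfig,
    trials: pd.DataFrame,
    truth: GroundTruth,
    noise_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """4-D BOLD series: HRF-convolved cue-period effects plus structured noise.

    Signal per voxel = sum over effects of amplitude x trial modulator,
    entering as a 6 s cue-period boxcar convolved with the canonical
    double-gamma HRF.  Modulators: rating for ``value_linear``,
    (rating - 5)^2 for ``saliency_quadratic``, 1 for ``mean_offset`` and for
    the category pattern (whose spatial profile varies by category).

    Effects are injected on non-actualized, rated cue events only — the
    events the analyses model parametrically — so the analysis GLM nests the
    forward model exactly and noiseless betas equal injected amplitudes.
    """
    if trials["cue_onset_s"].iloc[-1] + config.trial_length_s > n_scans_for(config, trials) * config.tr_s:
        raise ValueError("trial schedule extends beyond series duration")
    n_scans = n_scans_for(config, trials)
    shape = config.grid_shape
    series = np.zeros((*shape, n_scans), dtype=np.float32)

    onsets = trials["cue_onset_s"].to_numpy()
    dur = config.trial_length_s / 2.0
    rating = trials["rating"].to_numpy(dtype=float)
    rated = ~np.isnan(rating)
    nact = rated & ~trials["actualized"].to_numpy(dtype=bool)

    def add_component(spatial: np.ndarray, weights: np.ndarray, keep) -> None:
        if not np.any(spatial):
            return
        reg = convolve_events(onsets[keep], np.full(keep.sum(), dur), weights[keep], n_scans, config.tr_s)
        series[spatial != 0] += np.outer(
            spatial[spatial != 0], reg
        ).astype(np.float32)

    add_component(truth.mean_offset, np.ones(len(trials)), nact)
    add_component(truth.value_slope, rating, nact)
    add_component(truth.saliency_coef, (rating - NEUTRAL_RATING) ** 2, nact)
    if truth.category_patterns:
        weights = category_condition_weights(trials, truth.ortho_category_to_value)
        cond_idx = list(zip(trials["category"], trials["level"]))
        for cat, pat in truth.category_patterns.items():
            w_trial = np.asarray([weights.loc[ci, cat] for ci in cond_idx])
            add_component(pat, w_trial, nact)

    if noise_rng is not None:
        series = series + make_noise(config, n_scans, noise_rng).astype(np.float32)
    return series


def condition_modulators(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean rating and saliency over non-actualized, rated trials."""
    t = trials[~trials["actualized"] & trials["rating"].notna()].copy()
    t["saliency"] = (t["rating"] - NEUTRAL_RATING) ** 2
    out = (
        t.groupby(["category", "level"], sort=False)[["rating", "saliency"]]
        .mean()
        .reindex(pd.MultiIndex.from_tuples(CONDITIONS, names=["category", "level"]))
    )
    return out


def generate_condition_betas(
    config: StudyConfig,
    trials: pd.DataFrame,
    truth: GroundTruth,
    noise_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Directly emit the 16 condition beta volumes the cond16 GLM would recover.

    Condition beta = value_slope x mean rating + saliency_coef x mean
    saliency + mean_offset + category pattern, plus spatially smoothed
    Gaussian beta noise of SD ``noise.sigma``.  Shape ``(16, *grid_shape)``.
    """
    mods = condition_modulators(trials)
    weights = (
        category_condition_weights(trials, truth.ortho_category_to_value)
        if truth.category_patterns
        else None
    )
    betas = np.zeros((16, *config.grid_shape))
    for i, (cat, lvl) in enumerate(CONDITIONS):
        mr, ms = mods.loc[(cat, lvl), "rating"], mods.loc[(cat, lvl), "saliency"]
        if np.isnan(mr):
            raise ValueError(f"condition {cat}{lvl} has no rated non-actualized trials")
        betas[i] = (
            truth.mean_offset
            + truth.value_slope * mr
            + truth.saliency_coef * ms
        )
        for pcat, pat in truth.category_patterns.items():
            betas[i] = betas[i] + weights.loc[(cat, lvl), pcat] * pat
    if noise_rng is not None:
        betas += _smooth_noise_volume(config, noise_rng, 16)
    return betas


# ---------------------------------------------------------------------------
# Cohorts


def _subject_bundle(config: StudyConfig, seed_seq, betas_only: bool):
    trials = generate_ratings(config, seed_seq)
    truth = make_ground_truth(config, seed_seq)
    noise_rng = _rng(
        np.random.SeedSequence(entropy=_entropy_of(seed_seq), spawn_key=(3,))
    )
    if betas_only:
        data = generate_condition_betas(config, trials, truth, noise_rng)
    else:
        data = generate_bold(config, trials, truth, noise_rng)
    return trials, data, truth


def generate_cohort(config: StudyConfig, betas_only: bool = False):
    """Generate ``n_subjects`` independent subject bundles from the master seed.

    Returns a list of ``(trials, data, truth)`` triples; ``data`` is a 4-D
    time series, or a ``(16, *grid)`` beta stack when ``betas_only``.
    """
    out = []
    for i, ss in enumerate(config.subject_seeds()):
        trials, data, truth = _subject_bundle(config, ss, betas_only)
        trials.insert(0, "subject_id", i)
        out.append((trials, data, truth))
    return out


def generate_beta_cohort(config: StudyConfig):
    """Shorthand for :func:`generate_cohort` with ``betas_only=True``."""
    return generate_cohort(config, betas_only=True)
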