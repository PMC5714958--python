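"""First-level GLMs and group-level random-effects maps with cluster-extent FWE.

The univariate pathway: preprocess the BOLD series (linear detrend, discrete
cosine high-pass at three cycles per scan, optional Gaussian smoothing,
voxelwise z-transform), fit voxelwise OLS against an HRF-convolved design,
take single-subject coefficients to a one-sample t test across subjects, and
control family-wise error with a Monte-Carlo cluster-extent threshold that
accounts for the estimated spatial smoothness of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import CATEGORIES, CONDITIONS, NEUTRAL_RATING

__all__ = [
    "double_gamma_hrf",
    "convolve_events",
    "preprocess",
    "DesignMatrix",
    "build_design",
    "fit_ols",
    "group_ttest",
    "estimate_smoothness",
    "cluster_threshold",
    "apply_threshold",
    "conjunction",
    "Cluster",
]

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))


def double_gamma_hrf(
    dt: float,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_undershoot_ratio: float = 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, sampled every ``dt`` seconds.

    Response gamma peaks at ``peak_delay_s``, undershoot gamma at
    ``undershoot_delay_s``, with peak/undershoot amplitude ratio
    ``peak_undershoot_ratio``; normalized to unit integral.
    """
    t = np.arange(0.0, length_s, dt)
    # gamma with unit scale peaks at shape-1: shape = delay + 1
    peak = stats.gamma.pdf(t, peak_delay_s + 1.0)
    under = stats.gamma.pdf(t, undershoot_delay_s + 1.0)
    h = peak - under / peak_undershoot_ratio
    integral = h.sum() * dt
    return h / integral


def convolve_events(
    onsets_s: np.ndarray,
    durations_s: np.ndarray,
    weights: np.ndarray,
    n_scans: int,
    tr_s: float,
    oversample: int = 10,
    **hrf_kwargs,
) -> np.ndarray:
    """HRF-convolved regressor for weighted boxcar events, sampled at the TR.

    Events are laid out on an oversampled time grid (``tr_s / oversample``),
    convolved with the double-gamma HRF, and decimated at frame times.
    """
    dt = tr_s / oversample
    n_fine = n_scans * oversample
    stim = np.zeros(n_fine)
    for onset, dur, w in zip(onsets_s, durations_s, weights):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + dur) / dt))
        if i0 >= n_fine:
            raise ValueError(f"event onset {onset} s beyond series duration")
        stim[i0 : min(i1, n_fine)] += w
    hrf = double_gamma_hrf(dt, **hrf_kwargs)
    reg = np.convolve(stim, hrf)[:n_fine] * dt
    return reg[::oversample]


# ---------------------------------------------------------------------------
# Preprocessing


def dct_highpass_basis(n_scans: int, n_cycles: int = 3) -> np.ndarray:
    """Discrete cosine drift basis covering frequencies up to ``n_cycles``/scan."""
    t = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_scans)) for k in range(1, 2 * n_cycles + 1)]
    return np.column_stack(cols)


def preprocess(
    series: np.ndarray,
    voxel_size_mm=(3.0, 3.0, 4.0),
    smooth_fwhm_mm: float = 0.0,
    highpass_cycles: int = 3,
    zscore: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Detrend, high-pass, optionally smooth, and z-transform a 4-D series.

    Per voxel: the linear trend and discrete-cosine drift components at or
    below ``highpass_cycles`` cycles per scan are regressed out; the series
    is then optionally smoothed spatially (volume by volume) and finally
    z-transformed so each voxel has mean 0 and SD 1 — GLM betas are thereby
    on a z-score scale.  Returns ``(clean_series, valid_mask)`` where voxels
    with zero residual variance are flagged invalid (and left at zero).
    """
    series = np.asarray(series, dtype=float)
    n_scans = series.shape[-1]
    if n_scans < 8:
        raise ValueError("series too short to preprocess (need >= 8 scans)")
    t = np.arange(n_scans)
    drift = np.column_stack(
        [np.ones(n_scans), t - t.mean(), dct_highpass_basis(n_scans, highpass_cycles)]
    )
    q, _ = np.linalg.qr(drift)
    flat = series.reshape(-1, n_scans)
    flat = flat - (flat @ q) @ q.T
    out = flat.reshape(series.shape)
    if smooth_fwhm_mm > 0:
        sig = [smooth_fwhm_mm / _FWHM_TO_SD / vs for vs in voxel_size_mm]
        out = ndimage.gaussian_filter(out, sigma=sig + [0.0])
    sd = out.std(axis=-1)
    valid = sd > 1e-12
    if zscore:
        out = np.where(valid[..., None], out - out.mean(-1, keepdims=True), 0.0)
        out = np.divide(out, np.where(valid, sd, 1.0)[..., None])
    return out, valid


# ---------------------------------------------------------------------------
# Design matrices


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # n_scans x n_regressors
    names: list[str]
    is_task: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.is_task is None:
            self.is_task = np.ones(self.matrix.shape[1], dtype=bool)

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


DESIGN_VARIANTS = ("main", "rating9", "cond16", "category")


def build_design(
    trials: pd.DataFrame,
    n_scans: int,
    tr_s: float,
    variant: str = "main",
    cue_duration_s: float = 6.0,
    motion: np.ndarray | None = None,
    oversample: int = 10,
) -> DesignMatrix:
    """First-level design for one subject.

    Variants
    --------
    ``main``
        Eight task regressors: non-actualized cue (binary) with demeaned
        value and saliency parametric modulators; actualized cue (binary);
        actualized outcome (binary) with demeaned outcome value and saliency
        modulators; non-actualized outcome (binary).
    ``rating9``
        One binary cue regressor per observed pleasantness rating level,
        plus nuisance regressors for actualized cues and all outcomes.
    ``cond16``
        One binary cue regressor per non-actualized (category, level)
        condition, plus the same nuisance set.
    ``category``
        Binary cue regressors per category, controlling for (demeaned)
        value and saliency modulators, plus the nuisance set.

    Missed trials (rating NaN) are excluded from task regressors and modeled
    by one dedicated binary regressor covering the whole trial.  Motion
    parameters, when provided, are appended as nuisance columns.  An
    intercept is always included; unconvolved modulator weights sum to zero
    by construction (demeaning).
    """
    if variant not in DESIGN_VARIANTS:
        raise ValueError(f"unknown design variant {variant!r}")
    dur = cue_duration_s
    rating = trials["rating"].to_numpy(dtype=float)
    missed = np.isnan(rating)
    act = trials["actualized"].to_numpy(dtype=bool) & ~missed
    nact = ~trials["actualized"].to_numpy(dtype=bool) & ~missed
    cue_on = trials["cue_onset_s"].to_numpy(dtype=float)
    out_on = trials["outcome_onset_s"].to_numpy(dtype=float)
    value = rating
    saliency = (rating - NEUTRAL_RATING) ** 2

    cols: list[np.ndarray] = []
    names: list[str] = []
    task: list[bool] = []

    def reg(name, onsets, weights, is_task=True):
        if len(onsets) == 0:
            raise ValueError(f"regressor {name!r} references zero trials")
        cols.append(
            convolve_events(
                onsets, np.full(len(onsets), dur), weights, n_scans, tr_s, oversample
            )
        )
        names.append(name)
        task.append(is_task)

    def demean(x):
        return x - x.mean()

    if variant == "main":
        reg("na_cue", cue_on[nact], np.ones(nact.sum()))
        reg("na_cue_value", cue_on[nact], demean(value[nact]))
        reg("na_cue_saliency", cue_on[nact], demean(saliency[nact]))
        reg("a_cue", cue_on[act], np.ones(act.sum()))
        reg("a_outcome", out_on[act], np.ones(act.sum()))
        reg("a_outcome_value", out_on[act], demean(value[act]))
        reg("a_outcome_saliency", out_on[act], demean(saliency[act]))
        reg("na_outcome", out_on[nact], np.ones(nact.sum()))
    else:
        if variant == "rating9":
            for lvl in range(1, 10):
                sel = nact & (rating == lvl)
                if sel.any():
                    reg(f"rating{lvl}", cue_on[sel], np.ones(sel.sum()))
        elif variant == "cond16":
            cat_arr = trials["category"].to_numpy()
            lvl_arr = trials["level"].to_numpy()
            for cat, lvl in CONDITIONS:
                sel = nact & (cat_arr == cat) & (lvl_arr == lvl)
                if not sel.any():
                    raise ValueError(f"condition {cat}{lvl} has zero non-actualized trials")
                reg(f"{cat}{lvl}", cue_on[sel], np.ones(sel.sum()))
        elif variant == "category":
            cat_arr = trials["category"].to_numpy()
            for cat in CATEGORIES:
                sel = nact & (cat_arr == cat)
                if not sel.any():
                    raise ValueError(f"category {cat} has zero non-actualized trials")
                reg(f"cue_{cat}", cue_on[sel], np.ones(sel.sum()))
            reg("na_cue_value", cue_on[nact], demean(value[nact]))
            reg("na_cue_saliency", cue_on[nact], demean(saliency[nact]))
        # shared nuisance set
        reg("a_cue", cue_on[act], np.ones(act.sum()), is_task=False)
        reg("a_outcome", out_on[act], np.ones(act.sum()), is_task=False)
        reg("na_outcome", out_on[nact], np.ones(nact.sum()), is_task=False)

    if missed.any():
        cols.append(
            convolve_events(
                cue_on[missed],
                np.full(missed.sum(), 2 * dur),
                np.ones(missed.sum()),
                n_scans,
                tr_s,
                oversample,
            )
        )
        names.append("missed")
        task.append(False)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion{j}")
            task.append(False)

    cols.append(np.ones(n_scans))
    names.append("intercept")
    task.append(False)
    return DesignMatrix(np.column_stack(cols), names, np.asarray(task))


# ---------------------------------------------------------------------------
# OLS fitting


def fit_ols(
    series: np.ndarray, design: DesignMatrix, mask: np.ndarray | None = None
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Voxelwise ordinary least squares.

    Returns ``(betas, residuals)`` where ``betas`` maps each regressor name
    to a 3-D coefficient volume (NaN outside the mask) and ``residuals`` is
    the 4-D residual series (for smoothness estimation).  Raises on
    rank-deficient designs, naming the offending columns.
    """
    X = design.matrix
    n_scans = X.shape[0]
    if series.shape[-1] != n_scans:
        raise ValueError("series length does not match design")
    # rank check via QR: near-zero diagonal entries identify dependent columns
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < max(X.shape) * np.finfo(float).eps * diag.max()
    if bad.any():
        offenders = [design.names[i] for i in np.flatnonzero(bad)]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; dependent columns: {offenders}"
        )
    spatial = series.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    flat = series[mask]  # n_voxels x n_scans
    pinv = np.linalg.pinv(X)
    b = pinv @ flat.T  # n_reg x n_voxels
    resid_flat = flat.T - X @ b
    betas = {}
    for i, name in enumerate(design.names):
        vol = np.full(spatial, np.nan)
        vol[mask] = b[i]
        betas[name] = vol
    residuals = np.zeros(series.shape)
    residuals[mask] = resid_flat.T
    return betas, residuals


# ---------------------------------------------------------------------------
# Group inference


def group_ttest(beta_stack: np.ndarray, mask: np.ndarray | None = None):
    """Voxelwise one-sample t across subjects (random effects), df = n - 1.

    ``beta_stack``: array (n_subjects, *grid).  Voxels that are NaN in any
    subject, or with zero across-subject variance, are masked out (t = NaN).
    Returns ``(t_map, df)``.
    """
    beta_stack = np.asarray(beta_stack, dtype=float)
    n = beta_stack.shape[0]
    if n < 3:
        raise ValueError("group t test needs at least 3 subjects")
    valid = ~np.isnan(beta_stack).any(axis=0)
    if mask is not None:
        valid &= mask
    mean = beta_stack.mean(axis=0)
    sd = beta_stack.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~valid | (sd <= 0)] = np.nan
    return t, n - 1


def estimate_smoothness(
    residuals: np.ndarray, mask: np.ndarray, voxel_size_mm
) -> np.ndarray:
    """Per-axis spatial FWHM (mm) from first differences of normalized residuals.

    A Gaussian smoothing kernel of SD s gives neighbours at spacing d a
    correlation rho = exp(-d^2 / (4 s^2)), estimated via
    rho = 1 - var(diff) / (2 var); inverting, FWHM = d sqrt(-2 ln 2 / ln rho).
    Residuals are normalized per voxel, differences taken along each axis
    within the mask, and the variance ratio averaged over time.  Sub-voxel
    (or zero) estimates are legitimate for unsmoothed noise.
    """
    res = np.asarray(residuals, dtype=float)
    if res.ndim == 3:
        res = res[..., None]
    sd = res.std(axis=-1)
    ok = mask & (sd > 1e-12)
    norm = np.where(ok[..., None], res / np.where(ok, sd, 1.0)[..., None], np.nan)
    fwhm = []
    for ax, d in enumerate(voxel_size_mm):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(1, None)
        sl_b[ax] = slice(None, -1)
        diff = norm[tuple(sl_a)] - norm[tuple(sl_b)]
        vardiff = np.nanmean(diff**2)
        rho = 1.0 - vardiff / 2.0
        if not np.isfinite(rho) or rho <= 0:
            fwhm.append(0.0)
        else:
            fwhm.append(float(d * np.sqrt(-2.0 * np.log(2.0) / np.log(rho))))
    return np.asarray(fwhm)


def _sim_max_cluster_sizes(
    shape,
    mask: np.ndarray,
    fwhm_vox: np.ndarray,
    z_thresh: float,
    n_sims: int,
    rng: np.random.Generator,
    two_tailed: bool,
    structure: np.ndarray,
) -> np.ndarray:
    sigmas = np.asarray(fwhm_vox, dtype=float) / _FWHM_TO_SD
    n_mask = int(mask.sum())
    maxes = np.zeros(n_sims, dtype=int)
    for s in range(n_sims):
        field_ = rng.standard_normal(size=shape)
        if np.any(sigmas > 0):
            field_ = ndimage.gaussian_filter(field_, sigma=sigmas)
        vals = field_[mask]
        field_ = (field_ - vals.mean()) / vals.std()
        supra = (np.abs(field_) if two_tailed else field_) > z_thresh
        supra &= mask
        if not supra.any():
            continue
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            maxes[s] = int(np.bincount(labels.ravel())[1:].max())
    return maxes


def _connectivity(order: int) -> np.ndarray:
    if order not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[order])


def cluster_threshold(
    shape,
    mask: np.ndarray,
    fwhm_mm: np.ndarray,
    voxel_size_mm,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    n_sims: int = 1000,
    rng: np.random.Generator | None = None,
    two_tailed: bool = True,
    connectivity: int = 6,
) -> int:
    """Monte-Carlo cluster-extent threshold controlling FWE at ``alpha``.

    Simulates ``n_sims`` Gaussian random fields at the estimated smoothness
    inside the mask, binarizes at the z equivalent of ``voxel_p``, records
    the maximum cluster size of each field, and returns the smallest k with
    P(max cluster >= k) <= alpha.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng() if rng is None else rng
    z = stats.norm.isf(voxel_p / 2.0) if two_tailed else stats.norm.isf(voxel_p)
    fwhm_vox = np.asarray(fwhm_mm, dtype=float) / np.asarray(voxel_size_mm, dtype=float)
    maxes = _sim_max_cluster_sizes(
        shape, mask, fwhm_vox, z, n_sims, rng, two_tailed, _connectivity(connectivity)
    )
    # smallest k with P(max >= k) <= alpha
    for k in range(1, int(maxes.max()) + 2):
        if (maxes >= k).mean() <= alpha:
            return k
    return int(maxes.max()) + 1


@dataclass
class Cluster:
    voxels: np.ndarray  # (n, 3) indices
    size: int
    center_of_gravity: np.ndarray  # voxel coordinates, unweighted mean
    mean_stat: float
    peak_voxel: np.ndarray
    peak_stat: float

    def to_row(self) -> dict:
        return {
            "size": self.size,
            "cog_x": self.center_of_gravity[0],
            "cog_y": self.center_of_gravity[1],
            "cog_z": self.center_of_gravity[2],
            "mean_stat": self.mean_stat,
            "peak_x": int(self.peak_voxel[0]),
            "peak_y": int(self.peak_voxel[1]),
            "peak_z": int(self.peak_voxel[2]),
            "peak_stat": self.peak_stat,
        }


def apply_threshold(
    stat_map: np.ndarray,
    stat_thresh: float,
    cluster_k: int,
    two_tailed: bool = True,
    connectivity: int = 6,
) -> tuple[list[Cluster], np.ndarray]:
    """Label suprathreshold voxels into clusters and drop those below k.

    Positive and negative suprathreshold sets are labeled separately when
    two-tailed.  Returns ``(clusters, surviving_mask)``; clusters report
    size, unweighted center of gravity, mean statistic and peak.
    """
    stat = np.nan_to_num(stat_map, nan=0.0)
    structure = _connectivity(connectivity)
    signs = [1, -1] if two_tailed else [1]
    clusters: list[Cluster] = []
    surviving = np.zeros(stat.shape, dtype=bool)
    for sign in signs:
        supra = sign * stat > stat_thresh
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            if len(vox) < cluster_k:
                continue
            vals = stat[labels == lab]
            peak_i = np.argmax(sign * vals)
            clusters.append(
                Cluster(
                    voxels=vox,
                    size=len(vox),
                    center_of_gravity=vox.mean(axis=0),
                    mean_stat=float(vals.mean()),
                    peak_voxel=vox[peak_i],
                    peak_stat=float(vals[peak_i]),
                )
            )
            surviving[labels == lab] = True
    clusters.sort(key=lambda c: -c.size)
    return clusters, surviving


def clusters_to_table(clusters: list[Cluster]) -> pd.DataFrame:
    rows = [c.to_row() for c in clusters]
    cols = ["size", "cog_x", "cog_y", "cog_z", "mean_stat", "peak_x", "peak_y", "peak_z", "peak_stat"]
    return pd.DataFrame(rows, columns=cols)


def conjunction(
    map_a: np.ndarray,
    map_b: np.ndarray,
    stat_thresh: float,
    min_cluster: int = 1,
    connectivity: int = 6,
) -> np.ndarray:
    """Voxels suprathreshold (positively) in both maps; small clusters removed."""
    if map_a.shape != map_b.shape:
        raise ValueError("conjunction maps must share a grid")
    both = (np.nan_to_num(map_a) > stat_thresh) & (np.nan_to_num(map_b) > stat_thresh)
    if min_cluster > 1:
        labels, n_lab = ndimage.label(both, structure=_connectivity(connectivity))
        keep = np.zeros_like(both)
        for lab in range(1, n_lab + 1):
            sel = labels == lab
            if sel.sum() >= min_cluster:
                keep |= sel
        both = keep
    return both
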