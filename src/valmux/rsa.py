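"""Searchlight representational similarity analysis of 16 cue conditions.

Neural RDMs are 16 x 16 Pearson correlational distances between condition
patterns (d = 1 - corr, insensitive to shared scaling and offsets of the
voxel patterns, hence blind to mean-activation differences).  Eight model
RDMs express hypotheses about what the patterns encode: category identity,
value, saliency, category mean value, modality (primary vs secondary),
valence (positive vs negative), money/face/shock, and gains/losses/primary.
Neural and model RDMs are compared by Spearman rank correlation over the
120 lower-triangle entries; group inference is a one-sided Wilcoxon
signed-rank test of rho > 0 across subjects, whose z is mapped to the
searchlight's center voxel.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .config import CONDITIONS, CONDITION_NAMES, NEUTRAL_RATING
from .behavior import modality_of, valence_of

__all__ = [
    "pearson_distance",
    "build_neural_rdm",
    "build_model_rdm",
    "MODEL_NAMES",
    "compare_rdms",
    "searchlight",
    "signed_rank_test",
    "group_inference",
]

_TRIL = np.tril_indices(16, k=-1)


def lower_triangle(rdm: np.ndarray) -> np.ndarray:
    """The 120 below-diagonal entries of a 16 x 16 RDM, row-major."""
    return np.asarray(rdm)[_TRIL]


def pearson_distance(bj: np.ndarray, bk: np.ndarray) -> float:
    """Pearson correlational distance d = 1 - corr(bj, bk), in [0, 2].

    Invariant to positive affine transforms of either pattern; undefined
    (ValueError) for constant patterns.
    """
    bj = np.asarray(bj, dtype=float)
    bk = np.asarray(bk, dtype=float)
    if bj.shape != bk.shape or bj.size < 2:
        raise ValueError("patterns must share a length >= 2")
    cj = bj - bj.mean()
    ck = bk - bk.mean()
    nj, nk = np.linalg.norm(cj), np.linalg.norm(ck)
    if nj == 0 or nk == 0:
        raise ValueError("correlation distance undefined for constant patterns")
    return float(1.0 - cj @ ck / (nj * nk))


def build_neural_rdm(patterns: np.ndarray) -> np.ndarray:
    """Neural RDM from a (16, m) condition-by-voxel pattern matrix.

    Symmetric, zero diagonal, entries in [0, 2].  Raises if any condition
    pattern is constant (its correlation is undefined) or missing (NaN).
    """
    p = np.asarray(patterns, dtype=float)
    if p.ndim != 2 or p.shape[0] != 16 or p.shape[1] < 2:
        raise ValueError("expected a (16, m>=2) pattern matrix")
    if np.isnan(p).any():
        raise ValueError("missing condition pattern; subject excluded from RSA")
    c = p - p.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1)
    if (norms == 0).any():
        bad = [CONDITION_NAMES[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"constant pattern for conditions {bad}")
    corr = (c @ c.T) / np.outer(norms, norms)
    rdm = 1.0 - corr
    np.fill_diagonal(rdm, 0.0)
    return (rdm + rdm.T) / 2.0


# ---------------------------------------------------------------------------
# Model RDMs

MODEL_NAMES = (
    "category",
    "value",
    "saliency",
    "category_mean_value",
    "primary_secondary",
    "positive_negative",
    "money_face_shock",
    "gains_losses_primary",
)


def _label_rdm(labels) -> np.ndarray:
    lab = np.asarray(labels)
    return (lab[:, None] != lab[None, :]).astype(float)


def build_model_rdm(
    model: str, condition_means: pd.DataFrame | None = None
) -> np.ndarray:
    """One of the eight model RDMs, in canonical condition order.

    ``condition_means`` (required for the rating-dependent models ``value``,
    ``saliency`` and ``category_mean_value``) is the per-subject table of
    per-condition mean rating and mean saliency over non-actualized cue
    trials, indexed by (category, level) as produced by
    :func:`valmux.synth.condition_modulators`.

    Categorical models are binary (0 within group, 1 between); continuous
    models use absolute differences of condition (or category) means.
    """
    cats = [c for c, _ in CONDITIONS]
    if model == "category":
        return _label_rdm(cats)
    if model == "primary_secondary":
        return _label_rdm([modality_of(c) for c in cats])
    if model == "positive_negative":
        return _label_rdm([valence_of(c) for c in cats])
    if model == "money_face_shock":
        return _label_rdm(["money" if c in ("gain", "loss") else c for c in cats])
    if model == "gains_losses_primary":
        return _label_rdm(["primary" if c in ("face", "shock") else c for c in cats])
    if model in ("value", "saliency", "category_mean_value"):
        if condition_means is None:
            raise ValueError(f"model {model!r} requires per-condition means")
        if model == "value":
            v = condition_means["rating"].to_numpy(dtype=float)
            return np.abs(v[:, None] - v[None, :])
        if model == "saliency":
            s = condition_means["saliency"].to_numpy(dtype=float)
            return np.abs(s[:, None] - s[None, :])
        # category_mean_value: 0 within category, |category mean rating
        # difference| between categories
        cat_mean = condition_means.groupby(level="category", sort=False)["rating"].mean()
        v = np.array([cat_mean[c] for c in cats])
        rdm = np.abs(v[:, None] - v[None, :])
        rdm[_label_rdm(cats) == 0] = 0.0
        return rdm
    raise ValueError(f"unknown model name {model!r}")


def compare_rdms(neural: np.ndarray, model: np.ndarray) -> float:
    """Spearman rho over the lower triangles (average ranks for ties)."""
    nv = lower_triangle(neural)
    mv = lower_triangle(model)
    if np.ptp(mv) == 0:
        raise ValueError("model RDM is constant; Spearman rho undefined")
    rho = stats.spearmanr(nv, mv).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Searchlight


def _neighbor_offsets(half_width: int) -> np.ndarray:
    r = range(-half_width, half_width + 1)
    return np.array([(i, j, k) for i in r for j in r for k in r])


def searchlight(
    betas: np.ndarray,
    mask: np.ndarray,
    model_rdms: dict[str, np.ndarray],
    cube_half_width: int = 1,
    min_voxels: int = 14,
) -> dict[str, np.ndarray]:
    """Per-voxel Spearman rho maps for one subject, one map per model.

    For each in-mask center voxel, the condition patterns are the in-mask
    voxels of the (2h+1)^3 cube around it (27 voxels at the default h = 1);
    centers with fewer than ``min_voxels`` in-mask neighbours, or with a
    constant condition pattern, are NaN.  ``betas`` has shape (16, *grid).

    The computation is vectorized across centers: patterns are gathered by
    integer offsets into a NaN-padded volume and masked correlations /
    tied-rank Spearman coefficients are evaluated in batch.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape[0] != 16:
        raise ValueError("expected 16 condition beta volumes")
    grid = betas.shape[1:]
    mask = np.asarray(mask, dtype=bool)
    offsets = _neighbor_offsets(cube_half_width)
    n_nb = len(offsets)

    centers = np.argwhere(mask)
    n_c = len(centers)
    # gather neighbours through a padded index volume
    pad = cube_half_width
    padded = np.full((16, *[g + 2 * pad for g in grid]), np.nan)
    padded[(slice(None),) + tuple(slice(pad, pad + g) for g in grid)] = np.where(
        mask, betas, np.nan
    )
    nb_idx = centers[:, None, :] + offsets[None, :, :] + pad  # (n_c, n_nb, 3)
    patt = padded[:, nb_idx[..., 0], nb_idx[..., 1], nb_idx[..., 2]]  # (16, n_c, n_nb)
    patt = np.moveaxis(patt, 0, 1)  # (n_c, 16, n_nb)

    w = ~np.isnan(patt[:, 0, :])  # (n_c, n_nb) voxel validity (same per condition)
    k = w.sum(axis=1)  # in-mask cube size per center
    ok = k >= min_voxels
    patt = np.nan_to_num(patt)
    kf = np.maximum(k, 1).astype(float)
    mean = patt.sum(axis=2) / kf[:, None]
    centered = (patt - mean[:, :, None]) * w[:, None, :]
    norms = np.sqrt((centered**2).sum(axis=2))  # (n_c, 16)
    ok &= (norms > 0).all(axis=1)
    safe_norms = np.where(norms > 0, norms, 1.0)
    corr = np.einsum("cim,cjm->cij", centered, centered) / (
        safe_norms[:, :, None] * safe_norms[:, None, :]
    )
    rdm_lower = (1.0 - corr)[:, _TRIL[0], _TRIL[1]]  # (n_c, 120)

    ranks = stats.rankdata(rdm_lower, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    rnorm = np.linalg.norm(ranks, axis=1)
    out: dict[str, np.ndarray] = {}
    for name, model in model_rdms.items():
        mv = lower_triangle(model)
        if np.ptp(mv) == 0:
            raise ValueError(f"model RDM {name!r} is constant")
        mr = stats.rankdata(mv)
        mr = mr - mr.mean()
        mnorm = np.linalg.norm(mr)
        rho = (ranks @ mr) / (rnorm * mnorm)
        vol = np.full(grid, np.nan)
        vol[tuple(centers[ok].T)] = rho[ok]
        out[name] = vol
    return out


# ---------------------------------------------------------------------------
# Group inference: one-sided Wilcoxon signed-rank


@lru_cache(maxsize=64)
def _signed_rank_sf(n: int) -> np.ndarray:
    """Exact null survival function of W+ for n untied nonzero differences.

    ``sf[w] = P(W+ >= w)`` for w = 0..n(n+1)/2, by the standard
    dynamic-programming enumeration of all 2^n sign assignments.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: max_w + 1 - r].copy()
    probs = counts / 2.0**n
    return probs[::-1].cumsum()[::-1]


def signed_rank_test(x: np.ndarray, exact_max_n: int = 30) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test of median > 0.

    Zero differences are dropped (standard convention); ties in |x| get
    average ranks.  Returns ``(z, p)`` where z is always from the normal
    approximation (with tie correction) and p is exact (full enumeration)
    when there are no ties or zeros and n <= ``exact_max_n``, else from the
    normal approximation.  All-zero input gives (0, 1).
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    nz = x[x != 0]
    m = len(nz)
    if m == 0:
        return 0.0, 1.0
    absx = np.abs(nz)
    ranks = stats.rankdata(absx)
    w_plus = float(ranks[nz > 0].sum())
    mu = m * (m + 1) / 4.0
    _, tie_counts = np.unique(absx, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    z = 0.0 if var == 0 else (w_plus - mu) / np.sqrt(var)
    no_ties = len(tie_counts) == m
    if no_ties and len(nz) == len(x) and m <= exact_max_n:
        p = float(_signed_rank_sf(m)[int(round(w_plus))])
    else:
        p = float(stats.norm.sf(z))
    return float(z), p


def group_inference(
    rho_stack: np.ndarray, min_subjects: int = 5, exact_max_n: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sided signed-rank test of rho > 0 across subjects.

    ``rho_stack``: (n_subjects, *grid) searchlight rho maps.  Returns
    ``(z_map, p_map)``; voxels with fewer than ``min_subjects`` defined rhos
    are NaN.  Fully-defined voxels with continuous (untied, nonzero) values
    go through a vectorized path with exact p-values; the remainder fall
    back to the scalar test.
    """
    rho = np.asarray(rho_stack, dtype=float)
    n_subj = rho.shape[0]
    grid = rho.shape[1:]
    flat = rho.reshape(n_subj, -1)
    z_flat = np.full(flat.shape[1], np.nan)
    p_flat = np.full(flat.shape[1], np.nan)

    n_def = (~np.isnan(flat)).sum(axis=0)
    full = (n_def == n_subj) & (flat != 0).all(axis=0)
    if full.any():
        x = flat[:, full]
        ranks = stats.rankdata(np.abs(x), axis=0)
        w_plus = np.where(x > 0, ranks, 0.0).sum(axis=0)
        m = n_subj
        mu = m * (m + 1) / 4.0
        var = m * (m + 1) * (2 * m + 1) / 24.0
        z = (w_plus - mu) / np.sqrt(var)
        # untied columns get exact p; assume continuity (ties negligible)
        tied = np.zeros(x.shape[1], dtype=bool)
        sorted_abs = np.sort(np.abs(x), axis=0)
        tied = (np.diff(sorted_abs, axis=0) == 0).any(axis=0)
        p = np.empty_like(z)
        if m <= exact_max_n:
            sf = _signed_rank_sf(m)
            p[~tied] = sf[np.round(w_plus[~tied]).astype(int)]
        else:
            p[~tied] = stats.norm.sf(z[~tied])
        if tied.any():
            for j in np.flatnonzero(tied):
                z[j], p[j] = signed_rank_test(x[:, j], exact_max_n)
        z_flat[full] = z
        p_flat[full] = p

    rest = ~full & (n_def >= min_subjects)
    for j in np.flatnonzero(rest):
        z_flat[j], p_flat[j] = signed_rank_test(flat[:, j], exact_max_n)
    return z_flat.reshape(grid), p_flat.reshape(grid)


def export_rdm(rdm: np.ndarray, path) -> None:
    """Write a 16 x 16 RDM as TSV with condition-label header (gain1..shock4)."""
    pd.DataFrame(rdm, index=CONDITION_NAMES, columns=CONDITION_NAMES).to_csv(
        path, sep="\t"
    )
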