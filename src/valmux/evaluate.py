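"""End-to-end validation runs on synthetic cohorts with known ground truth.

Each function generates a cohort under the canonical study conditions
(:mod:`valmux.scenarios`), pushes it through the corresponding analysis
pathway, and scores recovery against the injected effects (Dice overlap of
surviving clusters with the true ROIs, family-wise error rates, detection
rates).  Tests and the validation script call these; nothing here reads
ground truth during analysis — only for scoring.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import glm, pca, rsa, scenarios, synth
from .config import CATEGORIES, CONDITIONS, StudyConfig

__all__ = [
    "dice",
    "univariate_recovery",
    "fwe_null_rate",
    "rsa_multiplex_run",
    "searchlight_null_rate",
    "pca_multiplex_run",
    "anova_detection",
    "anova_null_pvalues",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 0.0


def smoothness_from_maps(stack: np.ndarray, mask: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Spatial FWHM of a group of subject maps, from their within-group residuals."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        resid = stack - np.nanmean(stack, axis=0)
    return glm.estimate_smoothness(np.moveaxis(resid, 0, -1), mask, voxel_size_mm)


def _group_cluster_map(
    beta_stack: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm,
    voxel_p: float,
    alpha: float,
    n_sims: int,
    rng: np.random.Generator,
    two_tailed: bool = True,
):
    """Group t map -> FWE cluster threshold -> surviving clusters/mask."""
    t_map, df = glm.group_ttest(beta_stack, mask)
    fwhm = smoothness_from_maps(beta_stack, mask, voxel_size_mm)
    k = glm.cluster_threshold(
        t_map.shape, mask, fwhm, voxel_size_mm, voxel_p, alpha, n_sims, rng,
        two_tailed=two_tailed,
    )
    t_crit = (
        stats.t.isf(voxel_p / 2.0, df) if two_tailed else stats.t.isf(voxel_p, df)
    )
    clusters, surviving = glm.apply_threshold(t_map, t_crit, k, two_tailed=two_tailed)
    return t_map, clusters, surviving, k


# ---------------------------------------------------------------------------
# Univariate pathway


def fit_subject_main(config: StudyConfig, trials, series, smooth_fwhm_mm: float = 6.0):
    """Preprocess (6 mm smoothing for the univariate path) and fit the main GLM."""
    clean, _ = glm.preprocess(series, config.voxel_size_mm, smooth_fwhm_mm)
    design = glm.build_design(trials, series.shape[-1], config.tr_s, "main")
    betas, resid = glm.fit_ols(clean, design)
    return betas, resid


def univariate_recovery(
    seed: int = 0,
    n_subjects: int = 12,
    grid: int = 24,
    n_sims: int = 500,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
) -> dict:
    """Value/saliency map recovery on the two-ROI time-series cohort.

    Fits the joint value + saliency GLM per subject, thresholds the group
    maps (per-voxel ``voxel_p``, cluster FWE ``alpha``) and reports Dice
    overlaps of each map's surviving clusters with both true ROIs.
    """
    cfg = scenarios.univariate_recovery_config(seed, n_subjects, grid)
    roi_a = scenarios.ROI_A(cfg.grid_shape)
    roi_b = scenarios.ROI_B(cfg.grid_shape)
    value_stack, saliency_stack = [], []
    for trials, series, _ in synth.generate_cohort(cfg):
        betas, _ = fit_subject_main(cfg, trials, series)
        value_stack.append(betas["na_cue_value"])
        saliency_stack.append(betas["na_cue_saliency"])
    mask = np.ones(cfg.grid_shape, dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    out = {}
    for name, stack, roi_own, roi_other in (
        ("value", np.asarray(value_stack), roi_a, roi_b),
        ("saliency", np.asarray(saliency_stack), roi_b, roi_a),
    ):
        _, clusters, surviving, k = _group_cluster_map(
            stack, mask, cfg.voxel_size_mm, voxel_p, alpha, n_sims, rng
        )
        out[f"{name}_dice_own"] = dice(surviving, roi_own)
        out[f"{name}_dice_other"] = dice(surviving, roi_other)
        out[f"{name}_cluster_threshold"] = k
        out[f"{name}_n_clusters"] = len(clusters)
    return out


def condition_value_slope(betas16: np.ndarray, mean_ratings: np.ndarray) -> np.ndarray:
    """Per-voxel regression slope of the 16 condition betas on condition value."""
    r = np.asarray(mean_ratings, dtype=float)
    rc = r - r.mean()
    return np.tensordot(rc, betas16, axes=(0, 0)) / (rc @ rc)


def fwe_null_rate(
    seed: int = 0,
    n_cohorts: int = 50,
    n_subjects: int = 12,
    grid: int = 24,
    n_sims: int = 500,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
) -> dict:
    """Fraction of null cohorts with any surviving value cluster.

    Cohorts are generated betas-only with no injected effects; the value
    map is the per-subject condition-beta-on-value slope, taken to the
    group cluster test.  Nominal FWE is ``alpha``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 88]))
    n_fp = 0
    for c in range(n_cohorts):
        cfg = scenarios.null_betas_config(seed * 10007 + c, n_subjects, grid)
        stack = []
        for trials, betas16, _ in synth.generate_cohort(cfg, betas_only=True):
            mods = synth.condition_modulators(trials)
            stack.append(condition_value_slope(betas16, mods["rating"].to_numpy()))
        mask = np.ones(cfg.grid_shape, dtype=bool)
        _, clusters, _, _ = _group_cluster_map(
            np.asarray(stack), mask, cfg.voxel_size_mm, voxel_p, alpha, n_sims, rng
        )
        n_fp += bool(clusters)
    return {"family_error_rate": n_fp / n_cohorts, "n_cohorts": n_cohorts}


# ---------------------------------------------------------------------------
# RSA pathway


def _category_contrast_stacks(beta_cohort: list[np.ndarray]) -> dict[str, np.ndarray]:
    """Per-category univariate contrasts (category mean minus rest) per subject."""
    idx_by_cat = {
        cat: [i for i, (c, _) in enumerate(CONDITIONS) if c == cat] for cat in CATEGORIES
    }
    out = {}
    for cat in CATEGORIES:
        sel = idx_by_cat[cat]
        rest = [i for i in range(16) if i not in sel]
        out[cat] = np.asarray(
            [b[sel].mean(axis=0) - b[rest].mean(axis=0) for b in beta_cohort]
        )
    return out


def _rsa_group_cluster(
    rho_stack: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm,
    voxel_p: float,
    alpha: float,
    n_sims: int,
    rng: np.random.Generator,
):
    """Signed-rank z map, one-sided thresholding, cluster FWE on the z map."""
    z_map, p_map = rsa.group_inference(rho_stack)
    fwhm = smoothness_from_maps(rho_stack, mask, voxel_size_mm)
    k = glm.cluster_threshold(
        z_map.shape, mask, fwhm, voxel_size_mm, voxel_p, alpha, n_sims, rng,
        two_tailed=False,
    )
    supra = np.nan_to_num(p_map, nan=1.0) < voxel_p
    from scipy import ndimage

    labels, n_lab = ndimage.label(supra, structure=ndimage.generate_binary_structure(3, 1))
    surviving = np.zeros(supra.shape, dtype=bool)
    for lab in range(1, n_lab + 1):
        selm = labels == lab
        if selm.sum() >= k:
            surviving |= selm
    return z_map, p_map, surviving, k


def rsa_multiplex_run(
    kind: str,
    seed: int = 0,
    n_subjects: int = 17,
    grid: int = 20,
    n_sims: int = 500,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
) -> dict:
    """One cohort of the RSA orthogonality scenario.

    ``kind='category_pattern'``: zero-mean category patterns in ROI-C —
    expect a category-model searchlight cluster over the ROI and no
    univariate category contrast there.  ``kind='rank1_value'``: a common
    spatial profile scaled by condition value — expect the reverse
    (univariate value cluster, no category-model RSA cluster).
    """
    if kind == "category_pattern":
        cfg = scenarios.rsa_category_config(seed, n_subjects, grid)
    elif kind == "rank1_value":
        cfg = scenarios.rsa_rank1_value_config(seed, n_subjects, grid)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    roi_c = scenarios.ROI_C(cfg.grid_shape)
    mask = np.ones(cfg.grid_shape, dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))

    cohort = synth.generate_cohort(cfg, betas_only=True)
    rho_stack, betas_all, slope_stack = [], [], []
    cat_model = rsa.build_model_rdm("category")
    for trials, betas16, _ in cohort:
        rho = rsa.searchlight(betas16, mask, {"category": cat_model})["category"]
        rho_stack.append(rho)
        betas_all.append(betas16)
        mods = synth.condition_modulators(trials)
        slope_stack.append(condition_value_slope(betas16, mods["rating"].to_numpy()))

    _, _, rsa_surviving, _ = _rsa_group_cluster(
        np.asarray(rho_stack), mask, cfg.voxel_size_mm, voxel_p, alpha, n_sims, rng
    )
    # univariate category contrasts: union of surviving clusters over categories
    univ_cat = np.zeros(cfg.grid_shape, dtype=bool)
    for cat, stack in _category_contrast_stacks(betas_all).items():
        _, _, surv, _ = _group_cluster_map(
            stack, mask, cfg.voxel_size_mm, voxel_p, alpha, n_sims, rng
        )
        univ_cat |= surv
    _, _, univ_val, _ = _group_cluster_map(
        np.asarray(slope_stack), mask, cfg.voxel_size_mm, voxel_p, alpha, n_sims, rng
    )
    return {
        "rsa_category_dice": dice(rsa_surviving, roi_c),
        "univ_category_dice": dice(univ_cat, roi_c),
        "univ_value_cover": float(univ_val[roi_c].mean()),
    }


def searchlight_null_rate(
    seed: int = 0, n_subjects: int = 17, grid: int = 20, voxel_p: float = 0.005
) -> dict:
    """Rate of group signed-rank p < voxel_p on pure-noise condition betas."""
    cfg = scenarios.rsa_null_config(seed, n_subjects, grid)
    mask = np.ones(cfg.grid_shape, dtype=bool)
    cat_model = rsa.build_model_rdm("category")
    rho_stack = [
        rsa.searchlight(betas16, mask, {"category": cat_model})["category"]
        for _, betas16, _ in synth.generate_cohort(cfg, betas_only=True)
    ]
    _, p_map = rsa.group_inference(np.asarray(rho_stack))
    defined = ~np.isnan(p_map)
    rate = float((p_map[defined] < voxel_p).mean())
    return {"null_rate": rate, "n_centers": int(defined.sum()), "nominal": voxel_p}


# ---------------------------------------------------------------------------
# PCA pathway


def pca_multiplex_run(seed: int = 0, n_subjects: int = 17, alpha: float = 0.05) -> dict:
    """One cohort of the PCA multiplexing scenario.

    A uniform value-scaled signal plus zero-mean category patterns share one
    ROI; covariance PCA per subject, then mixed-effects regressions of the
    first three components.  Reports whether PC1 carries value (and not
    category) and whether a later PC carries category.
    """
    cfg = scenarios.pca_roi_config(seed, n_subjects)
    roi = cfg.effects[0].roi
    results, cond_means = [], []
    for trials, betas16, _ in synth.generate_cohort(cfg, betas_only=True):
        matrix = betas16[:, roi]
        results.append(pca.fit_roi_pca(matrix, k=3))
        cond_means.append(synth.condition_modulators(trials))
    reg = [pca.pc_mixed_regression(results, cond_means, comp) for comp in range(3)]
    dummies = ("gain", "loss", "face")

    def pvals(table, terms):
        return {t: float(table.loc[table.term == t, "p"].iloc[0]) for t in terms}

    pc1 = pvals(reg[0], ("value", "saliency", "category_joint") + dummies)
    later_cat = min(pvals(r, ("category_joint",))["category_joint"] for r in reg[1:])
    return {
        "pc1_value_p": pc1["value"],
        "pc1_saliency_p": pc1["saliency"],
        "pc1_category_joint_p": pc1["category_joint"],
        "pc1_min_dummy_p": min(pc1[d] for d in dummies),
        "later_pc_category_p": later_cat,
        "pc1_value_only": bool(
            pc1["value"] < alpha and pc1["category_joint"] >= alpha
        ),
        "later_pc_category": bool(later_cat < alpha),
        "top3_variance_pct": float(
            100.0 * np.mean([r.variance_fraction.sum() for r in results])
        ),
        "pc1_variance_pct": float(
            100.0 * np.mean([r.variance_fraction[0] for r in results])
        ),
    }


# ---------------------------------------------------------------------------
# Behavioral pathway


def anova_detection(seed: int = 0, n_subjects: int = 18) -> float:
    """Valence x magnitude interaction p for one behavioural cohort."""
    from . import behavior

    cfg = scenarios.behavior_config(seed, n_subjects)
    tables = []
    for i, ss in enumerate(cfg.subject_seeds()):
        t = synth.generate_ratings(cfg, ss)
        t.insert(0, "subject_id", i)
        tables.append(t)
    import pandas as pd

    trials = pd.concat(tables, ignore_index=True)
    table, _ = behavior.cell_means_with_outlier_removal(trials)
    res = behavior.rm_anova(table)
    return float(res.loc[res.effect == "valence*magnitude", "p"].iloc[0])


def anova_null_pvalues(seed: int = 0, n_reps: int = 200, n_subjects: int = 18) -> np.ndarray:
    """Interaction p-values over repeated null (zero-slope) cohorts."""
    from . import behavior
    import pandas as pd

    ps = []
    for r in range(n_reps):
        cfg = scenarios.behavior_config(seed * 100003 + r, n_subjects, null=True)
        tables = []
        for i, ss in enumerate(cfg.subject_seeds()):
            t = synth.generate_ratings(cfg, ss)
            t.insert(0, "subject_id", i)
            tables.append(t)
        trials = pd.concat(tables, ignore_index=True)
        table = behavior.cell_means(trials)
        res = behavior.rm_anova(table)
        ps.append(float(res.loc[res.effect == "valence*magnitude", "p"].iloc[0]))
    return np.asarray(ps)
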