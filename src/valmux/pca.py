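"""ROI principal component analysis of 16-condition activation patterns.

Per subject, the 16 x m (conditions x voxels) beta matrix of an ROI is
decomposed by covariance PCA (per-voxel centering across conditions, no
variance scaling).  A first component with near-uniform positive loadings
behaves like the ROI mean activity; later components with mixed-sign
loadings capture multi-voxel pattern codes.  Mixed-effects regressions of
component scores on value, saliency and category dummies (shock as the
reference category) test which signals each component multiplexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CONDITIONS

__all__ = [
    "PcaResult",
    "fit_roi_pca",
    "loading_histogram",
    "pc_mixed_regression",
]


@dataclass
class PcaResult:
    scores: np.ndarray  # 16 x K condition scores
    loadings: np.ndarray  # m x K voxel loadings, unit norm per component
    variance_fraction: np.ndarray  # K, of the total variance
    voxel_means: np.ndarray  # m, per-voxel means removed before the SVD

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """scores @ loadings.T + voxel means; exact when K = rank."""
        return self.scores @ self.loadings.T + self.voxel_means


def fit_roi_pca(matrix: np.ndarray, k: int = 3) -> PcaResult:
    """Covariance PCA of a (16, m) condition-by-voxel beta matrix.

    Observations are the 16 conditions, variables the m voxels; each voxel
    is centered across conditions.  Components are ordered by explained
    variance; the sign convention makes the largest-magnitude loading of
    each component positive.  For a mean-activity-like component (loadings
    of one sign) this is equivalent to requiring a non-negative mean
    loading, but unlike the mean rule it stays deterministic and stable for
    mixed-sign pattern components, whose mean loading is near zero — a
    coin-flip orientation there would scramble score signs across subjects
    and erase group-level effects.  Variance fractions are eigenvalue
    shares of the total variance.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] != 16:
        raise ValueError("expected a (16, m) matrix")
    m = x.shape[1]
    if m < 4:
        raise ValueError("ROI too small for PCA (need >= 4 voxels)")
    if np.isnan(x).any():
        raise ValueError("missing conditions/voxels in the pattern matrix")
    if k > min(15, m):
        raise ValueError(f"k = {k} exceeds the available rank min(15, {m})")
    means = x.mean(axis=0)
    xc = x - means
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ev = s**2
    total = ev.sum()
    frac = ev / total if total > 0 else np.zeros_like(ev)
    loadings = vt[:k].T  # m x K, unit norm columns
    scores = u[:, :k] * s[:k]
    peak = np.argmax(np.abs(loadings), axis=0)
    flip = loadings[peak, np.arange(k)] < 0
    loadings[:, flip] *= -1
    scores[:, flip] *= -1
    return PcaResult(scores, loadings, frac[:k], means)


def loading_histogram(
    results: list[PcaResult], bins: int = 20
) -> tuple[np.ndarray, pd.DataFrame]:
    """Average loading-coefficient histogram across subjects, per component.

    Shared equal-width bin edges span the pooled loading range of all
    subjects; frequencies (normalized to sum to 1 within subject and
    component) are computed per subject, then averaged, with the SEM across
    subjects.  Returns ``(bin_edges, table)`` with columns component, bin,
    mean_frequency, sem.
    """
    if len(results) < 1:
        raise ValueError("need at least one subject")
    n_comp = results[0].n_components
    pooled = np.concatenate([r.loadings.ravel() for r in results])
    edges = np.linspace(pooled.min(), pooled.max(), bins + 1)
    rows = []
    for comp in range(n_comp):
        freqs = []
        for r in results:
            h, _ = np.histogram(r.loadings[:, comp], bins=edges)
            freqs.append(h / h.sum())
        freqs = np.asarray(freqs)
        mean = freqs.mean(axis=0)
        sem = (
            freqs.std(axis=0, ddof=1) / np.sqrt(len(freqs))
            if len(freqs) > 1
            else np.zeros(bins)
        )
        for b in range(bins):
            rows.append(
                {"component": comp + 1, "bin": b, "bin_left": edges[b],
                 "bin_right": edges[b + 1], "mean_frequency": mean[b], "sem": sem[b]}
            )
    return edges, pd.DataFrame(rows)


def _scores_long(
    results: list[PcaResult], condition_means: list[pd.DataFrame], component: int
) -> pd.DataFrame:
    rows = []
    for subj, (res, cm) in enumerate(zip(results, condition_means)):
        for i, (cat, lvl) in enumerate(CONDITIONS):
            rows.append(
                {
                    "subject_id": subj,
                    "score": res.scores[i, component],
                    "value": cm.loc[(cat, lvl), "rating"],
                    "saliency": cm.loc[(cat, lvl), "saliency"],
                    "gain": float(cat == "gain"),
                    "loss": float(cat == "loss"),
                    "face": float(cat == "face"),
                }
            )
    return pd.DataFrame(rows)


def pc_mixed_regression(
    results: list[PcaResult],
    condition_means: list[pd.DataFrame],
    component: int = 0,
) -> pd.DataFrame:
    """Mixed-effects regression of one component's scores on task variables.

    score ~ value + saliency + gain + loss + face + (1 | subject); the three
    category dummies code gain/loss/face against the shock reference.
    ``condition_means`` supplies each subject's per-condition mean rating and
    saliency (non-actualized cue trials).  A value-minus-saliency coefficient
    contrast row is included.  Singular mixed fits fall back to a
    subject-demeaned fixed-effects regression (flagged in the result).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if len(results) < 5:
        raise ValueError("mixed regression needs >= 5 subjects")
    df = _scores_long(results, condition_means, component)
    terms = ["value", "saliency", "gain", "loss", "face"]
    fallback = False
    try:
        fit = smf.mixedlm(
            "score ~ value + saliency + gain + loss + face", df, groups=df["subject_id"]
        ).fit(reml=True, method="lbfgs")
        if not np.isfinite([fit.bse.get(t, np.nan) for t in terms]).all():
            raise ValueError("singular mixed fit")
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
        cov = fit.cov_params()
    except Exception:
        fallback = True
        d = df.copy()
        for c in ["score"] + terms:
            d[c] = d[c] - d.groupby("subject_id")[c].transform("mean")
        x = sm.add_constant(d[terms])
        ols = sm.OLS(d["score"], x).fit()
        params, bse, pvals = ols.params, ols.bse, ols.pvalues
        cov = ols.cov_params()
    rows = []
    for t in terms:
        est, se = float(params[t]), float(bse[t])
        rows.append(
            {"component": component + 1, "term": t, "estimate": est, "se": se,
             "t": est / se if se > 0 else np.nan, "p": float(pvals[t]),
             "fallback_ols": fallback}
        )
    # value vs saliency contrast
    est = float(params["value"] - params["saliency"])
    var = (
        float(cov.loc["value", "value"])
        + float(cov.loc["saliency", "saliency"])
        - 2.0 * float(cov.loc["value", "saliency"])
    )
    se = np.sqrt(var) if var > 0 else np.nan
    from scipy import stats as sps

    zstat = est / se if se and np.isfinite(se) else np.nan
    rows.append(
        {"component": component + 1, "term": "value_minus_saliency", "estimate": est,
         "se": se, "t": zstat, "p": float(2 * sps.norm.sf(abs(zstat))) if np.isfinite(zstat) else np.nan,
         "fallback_ols": fallback}
    )
    # joint Wald test of the category factor (all three dummies simultaneously)
    dummies = ["gain", "loss", "face"]
    b = np.asarray([params[d] for d in dummies], dtype=float)
    v = np.asarray(cov.loc[dummies, dummies], dtype=float)
    try:
        chi2 = float(b @ np.linalg.solve(v, b))
        p_joint = float(sps.chi2.sf(chi2, df=3))
    except np.linalg.LinAlgError:
        chi2, p_joint = np.nan, np.nan
    rows.append(
        {"component": component + 1, "term": "category_joint", "estimate": chi2,
         "se": np.nan, "t": np.nan, "p": p_joint, "fallback_ols": fallback}
    )
    return pd.DataFrame(rows)
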