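"""Behavioral analysis: trial-level value/saliency and the three-way RM ANOVA.

Value is the cue-period pleasantness rating (1-9); saliency is the squared
deviation of the rating from the neutral point 5, giving a U-shaped profile
over value.  Mean ratings per (category, level) cell feed a three-way
repeated-measures ANOVA with within-subject factors valence (reward vs
punishment), modality (primary vs secondary/monetary) and magnitude (level
1-4), with Mauchly's sphericity test per multi-df effect and conditional
Greenhouse-Geisser correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    LEVELS,
    NEUTRAL_RATING,
    PRIMARY_CATEGORIES,
    REWARD_CATEGORIES,
)

__all__ = [
    "compute_value_saliency",
    "cell_means",
    "flag_cell_outliers",
    "cell_means_with_outlier_removal",
    "shapiro_per_cell",
    "rm_anova",
]

#: (valence, modality) -> category; cell order used by the ANOVA
_FACTOR_MAP = {
    ("reward", "secondary"): "gain",
    ("reward", "primary"): "face",
    ("punishment", "secondary"): "loss",
    ("punishment", "primary"): "shock",
}
_VALENCES = ("reward", "punishment")
_MODALITIES = ("secondary", "primary")


def valence_of(category: str) -> str:
    return "reward" if category in REWARD_CATEGORIES else "punishment"


def modality_of(category: str) -> str:
    return "primary" if category in PRIMARY_CATEGORIES else "secondary"


def compute_value_saliency(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial value and saliency for non-actualized, rated trials.

    value = rating; saliency = (rating - 5)^2.  Trials with missing ratings
    are excluded (count available as ``result.attrs['n_excluded_missing']``).
    """
    if trials["rating"].isna().all():
        raise ValueError("all ratings are missing")
    keep = ~trials["actualized"].astype(bool) & trials["rating"].notna()
    out = trials.loc[keep].copy()
    out["value"] = out["rating"].astype(float)
    out["saliency"] = (out["rating"].astype(float) - NEUTRAL_RATING) ** 2
    out.attrs["n_excluded_missing"] = int(
        (~trials["actualized"].astype(bool) & trials["rating"].isna()).sum()
    )
    return out


def cell_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean rating per (category, level) cell, subjects as rows."""
    rated = trials[trials["rating"].notna()]
    table = rated.pivot_table(
        index="subject_id", columns=["category", "level"], values="rating", aggfunc="mean"
    )
    return table


def flag_cell_outliers(table: pd.DataFrame) -> list[tuple]:
    """Boxplot 1.5-IQR rule per cell across subjects (strict inequality).

    A cell value is an outlier when it lies strictly beyond
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] of that cell's across-subject distribution;
    with zero IQR nothing is flagged.  Returns (subject, category, level)
    triples.
    """
    flagged = []
    for col in table.columns:
        vals = table[col].dropna()
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        for subj, v in vals.items():
            if v < lo or v > hi:
                flagged.append((subj, col[0], col[1]))
    return flagged


def cell_means_with_outlier_removal(
    trials: pd.DataFrame,
) -> tuple[pd.DataFrame, list[tuple]]:
    """Cell-mean table with boxplot-flagged cells set to NaN.

    Requires at least two subjects.  Only flagged cells are removed; all
    other cells are untouched.
    """
    table = cell_means(trials)
    if len(table) < 2:
        raise ValueError("outlier flagging needs >= 2 subjects")
    flagged = flag_cell_outliers(table)
    table = table.copy()
    for subj, cat, lvl in flagged:
        table.loc[subj, (cat, lvl)] = np.nan
    return table, flagged


def shapiro_per_cell(table: pd.DataFrame) -> pd.DataFrame:
    """Shapiro-Wilk normality test per (category, level) cell across subjects.

    A reporting convenience only — nothing downstream gates on it.
    """
    rows = []
    for col in table.columns:
        vals = table[col].dropna().to_numpy()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            res = stats.shapiro(vals)
            w, p = float(res.statistic), float(res.pvalue)
        else:
            w, p = np.nan, np.nan
        rows.append({"category": col[0], "level": col[1], "W": w, "p": p, "n": len(vals)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA machinery


def _orthonormal_poly(k: int) -> np.ndarray:
    """(k-1) x k orthonormal polynomial contrast rows for k ordered levels."""
    x = np.arange(1, k + 1, dtype=float)
    v = np.vander(x, k, increasing=True)  # columns 1, x, x^2, ...
    q, _ = np.linalg.qr(v)
    return q[:, 1:].T


def _effect_contrasts() -> dict[str, np.ndarray]:
    """Orthonormal contrast matrices (q x 16) per effect, cells ordered
    (valence, modality, level) with valence slowest."""
    c2 = np.array([[1.0, -1.0]]) / np.sqrt(2.0)
    j2 = np.ones((1, 2)) / np.sqrt(2.0)
    p4 = _orthonormal_poly(4)
    j4 = np.ones((1, 4)) / 2.0
    effects = {
        "valence": (c2, j2, j4),
        "modality": (j2, c2, j4),
        "magnitude": (j2, j2, p4),
        "valence*modality": (c2, c2, j4),
        "valence*magnitude": (c2, j2, p4),
        "modality*magnitude": (j2, c2, p4),
        "valence*modality*magnitude": (c2, c2, p4),
    }
    return {
        name: np.kron(np.kron(a, b), c) for name, (a, b, c) in effects.items()
    }


def _anova_cell_matrix(table: pd.DataFrame, impute: bool) -> np.ndarray:
    """Subjects x 16 matrix in (valence, modality, level) cell order.

    Missing cells (removed outliers) are mean-imputed from the remaining
    subjects when ``impute``; otherwise subjects with any missing cell are
    dropped (listwise deletion).
    """
    cols = [
        (_FACTOR_MAP[(val, mod)], lvl)
        for val in _VALENCES
        for mod in _MODALITIES
        for lvl in LEVELS
    ]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"incomplete design: missing cells {missing}")
    y = table[cols].to_numpy(dtype=float)
    if impute:
        col_means = np.nanmean(y, axis=0)
        nan_pos = np.isnan(y)
        y[nan_pos] = np.take(col_means, np.nonzero(nan_pos)[1])
    else:
        y = y[~np.isnan(y).any(axis=1)]
    return y


def rm_anova(
    table: pd.DataFrame,
    outlier_policy: str = "impute",
    gg_if_mauchly_p_below: float = 0.05,
) -> pd.DataFrame:
    """Three-way (2 x 2 x 4) within-subject ANOVA on the cell-mean table.

    For each effect, orthonormalized contrast scores Z (subjects x q) give
    F = n Zbar' Zbar / q divided by tr(S)/q with S the sample covariance of
    Z, on (q, q(n-1)) df.  For q > 1 effects, Mauchly's test is computed
    from S and, when its p falls below ``gg_if_mauchly_p_below``, the
    Greenhouse-Geisser epsilon multiplies both df (mirroring conditional
    correction).  Returns a tidy table with one row per effect.
    """
    if outlier_policy not in ("impute", "listwise"):
        raise ValueError("outlier_policy must be 'impute' or 'listwise'")
    y = _anova_cell_matrix(table, impute=outlier_policy == "impute")
    n = y.shape[0]
    if n < 3:
        raise ValueError("rm_anova needs at least 3 subjects")
    rows = []
    for name, m in _effect_contrasts().items():
        z = y @ m.T  # n x q
        q = z.shape[1]
        zbar = z.mean(axis=0)
        s = np.cov(z, rowvar=False, ddof=1).reshape(q, q)
        num = n * float(zbar @ zbar) / q
        den = float(np.trace(s)) / q
        f = num / den
        df1, df2 = float(q), float(q * (n - 1))
        eps = np.nan
        mauchly_chi2 = np.nan
        mauchly_p = np.nan
        if q > 1:
            eps = float(np.trace(s)) ** 2 / (q * float(np.sum(s * s)))
            # Mauchly's W with the chi-square approximation
            sign, logdet = np.linalg.slogdet(s)
            if sign <= 0:
                mauchly_p = 0.0
                mauchly_chi2 = np.inf
            else:
                log_w = logdet - q * np.log(np.trace(s) / q)
                fac = 1.0 - (2.0 * q * q + q + 2.0) / (6.0 * q * (n - 1.0))
                mauchly_chi2 = float(-(n - 1.0) * fac * log_w)
                df_m = q * (q + 1) / 2.0 - 1.0
                mauchly_p = float(stats.chi2.sf(mauchly_chi2, df_m))
        corrected = q > 1 and mauchly_p < gg_if_mauchly_p_below
        if corrected:
            df1, df2 = df1 * eps, df2 * eps
        p = float(stats.f.sf(f, df1, df2))
        rows.append(
            {
                "effect": name,
                "F": f,
                "df_num": df1,
                "df_den": df2,
                "p": p,
                "gg_epsilon": eps,
                "gg_applied": bool(corrected),
                "mauchly_chi2": mauchly_chi2,
                "mauchly_p": mauchly_p,
                "n_subjects": n,
            }
        )
    return pd.DataFrame(rows)
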