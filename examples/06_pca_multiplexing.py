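"""PCA evidence for multiplexed value and category codes in one ROI.

A uniform value-scaled signal and zero-mean category patterns share one
ROI.  Covariance PCA of each subject's 16 x voxels beta matrix yields a
mean-activity-like PC1 (narrow positive loadings) and pattern-like later
PCs; mixed-effects regressions of the component scores on value, saliency
and category dummies (shock as reference) show which signal each component
carries.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np
import pandas as pd

from valmux import pca, scenarios, synth

cfg = scenarios.pca_roi_config(seed=2)
roi = cfg.effects[0].roi
results, cond_means = [], []
for trials, betas16, _ in synth.generate_cohort(cfg, betas_only=True):
    results.append(pca.fit_roi_pca(betas16[:, roi], k=3))
    cond_means.append(synth.condition_modulators(trials))

var = np.array([r.variance_fraction for r in results])
print("variance explained (mean over subjects):",
      np.round(100 * var.mean(axis=0), 1), "%")
frac_pos = np.mean([(r.loadings[:, 0] > 0).mean() for r in results])
print(f"fraction of positive PC1 loadings: {frac_pos:.2f}")

tables = [pca.pc_mixed_regression(results, cond_means, c) for c in range(3)]
tab = pd.concat(tables, ignore_index=True)
show = tab[tab.term.isin(["value", "saliency", "category_joint"])]
print(show[["component", "term", "estimate", "p"]].round(4).to_string(index=False))
print()
print("PC1: value significant, category joint test not; PC2/PC3: category")
print("significant — the two codes are multiplexed but separable.")
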