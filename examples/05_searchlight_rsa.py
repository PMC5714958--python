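"""Whole-brain searchlight RSA of a multi-voxel category code.

Zero-mean category patterns are injected into a central ROI of a betas-only
cohort.  Per subject, every 27-voxel searchlight yields a 16 x 16 Pearson-
distance neural RDM compared with the category model RDM by Spearman rho;
a one-sided signed-rank test across subjects produces the group z map,
thresholded at voxel p < 0.005 with cluster-extent FWE control.  Because the
patterns are zero-mean, the univariate category contrast sees nothing.
"""

from valmux import evaluate

res = evaluate.rsa_multiplex_run("category_pattern", seed=5, n_subjects=12,
                                 grid=14, n_sims=300)
print(f"category-model RSA cluster Dice with the true ROI: {res['rsa_category_dice']:.3f}")
print(f"univariate category contrast Dice with the ROI:    {res['univ_category_dice']:.3f}")
print()
print("The searchlight map recovers the pattern ROI (Dice >~ 0.4) while the")
print("univariate contrast stays empty: the code lives in the pattern, not")
print("in mean activation.")
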