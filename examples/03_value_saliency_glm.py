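"""Univariate value and saliency mapping with cluster-extent FWE control.

Simulates a small cohort with a linear value effect in one ROI and a
U-shaped saliency effect in another, fits the joint value + saliency GLM
per subject (demeaned parametric modulators on non-actualized cues,
canonical HRF, 6 mm smoothing), and thresholds the group t maps with a
Monte-Carlo cluster-extent threshold.  Dice overlap with the injected ROIs
measures recovery; the cross-overlap measures value/saliency confusion.
"""

from valmux import evaluate

res = evaluate.univariate_recovery(seed=11, n_subjects=8, grid=16, n_sims=300)
for k, v in res.items():
    print(f"{k}: {v:.3f}" if isinstance(v, float) else f"{k}: {v}")
print()
print("dice_own ~ 0.8-0.9: the surviving clusters sit on the injected ROI;")
print("dice_other ~ 0: value clusters barely touch the saliency ROI and")
print("vice versa, so the two parametric codes are mapped separately.")
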