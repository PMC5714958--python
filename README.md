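# valmux

Simulation and analysis of **multiplexed value, saliency and category codes**
in anticipation-phase fMRI.

## The scientific problem

When people anticipate a motivationally relevant outcome — winning or losing
money, seeing a pleasant face, receiving an electric shock — brain regions
such as vmPFC and ventral striatum respond. Three distinct signals are
entangled in that response:

- **value** *v*: the signed desirability of the outcome, operationalized as
  the trial's cue-period pleasantness rating on a 1–9 scale;
- **saliency** *s* = (*v* − 5)²: motivational significance regardless of
  sign, a U-shaped function of value around the neutral point 5;
- **category**: the outcome's kind (monetary gain, monetary loss, pleasant
  face, electric shock), crossing valence with modality.

Separating them needs analyses with different sensitivities. This package
implements, as a tested and reusable library, the full analysis chain for a
4-category × 4-level cue paradigm (96 trials in 4 blocks, ~1/3 actualized,
12 s trials, TR = 2 s):

1. **behavior** — trial-level value/saliency and a three-way
   repeated-measures ANOVA (valence × modality × magnitude) with the
   boxplot 1.5-IQR outlier rule, Mauchly's sphericity test and conditional
   Greenhouse–Geisser correction;
2. **glm** — voxelwise OLS on HRF-convolved designs with demeaned
   parametric value/saliency modulators; random-effects group t maps;
   Monte-Carlo **cluster-extent FWE** thresholding at the estimated map
   smoothness (per-voxel p < 0.005, FWE p < 0.05); conjunctions;
3. **roi** — non-circular **leave-one-subject-out** spherical ROI
   definition, ROI effect tests, and rating-binned activation profiles with
   mixed-effects slope tests;
4. **rsa** — whole-brain **searchlight representational similarity
   analysis**: 16×16 neural RDMs from Pearson correlational distance
   d(**b**ⱼ,**b**ₖ) = 1 − corr(**b**ⱼ,**b**ₖ) in 27-voxel cubes, eight
   model RDMs (category, value, saliency, category-mean-value,
   primary–secondary, positive–negative, money/face/shock,
   gains/losses/primary), Spearman lower-triangle scoring, and one-sided
   signed-rank group z maps (exact enumeration for small n);
5. **pca** — per-subject covariance PCA of 16-condition ROI patterns,
   loading histograms, and mixed-effects regressions of component scores on
   value, saliency and category dummies (shock as reference) — the test for
   **multiplexed** codes: a mean-activity value component coexisting with
   pattern-coded category components;
6. **synth** — a synthetic cohort generator that injects known value,
   saliency and category-pattern signals (HRF-convolved cue responses plus
   AR(1), spatially smoothed noise), so every stage above is testable
   without any scanner data. `scenarios` pins the canonical study
   conditions; `evaluate` scores recovery against the ground truth;
   `pipeline.run_all` orchestrates everything with cached, checksummed
   stages.

No acquisition-side preprocessing (motion correction, normalization) is
included; real inputs, when used, are preprocessed 4-D NIfTI volumes plus
trial tables.

## Worked example

`examples/06_pca_multiplexing.py` simulates 17 subjects with a uniform
value-scaled signal plus zero-mean category patterns sharing one ROI, runs
PCA per subject and the mixed-effects score regressions:

```
variance explained (mean over subjects): [81.2  5.2  4.6] %
fraction of positive PC1 loadings: 1.00
 component           term  estimate      p
         1          value   14.7490 0.0000
         1       saliency   -0.0039 0.7344
         1 category_joint    0.3917 0.9420
         2          value    0.0443 0.9358
         2       saliency   -0.0095 0.9324
         2 category_joint   13.2993 0.0040
         3          value    0.1988 0.6961
         3       saliency    0.0215 0.8411
         3 category_joint    0.2290 0.9728
```

PC1 explains ~81% of the variance with uniformly positive loadings — a
mean-activity component that tracks value (p < 10⁻⁴) but not saliency or
category. PC2 carries the category code (joint Wald p = 0.004) with no
value effect: the two signals are multiplexed in one region yet separable
by the decomposition. The other scripts in `examples/` demonstrate the
simulator, the ANOVA, univariate mapping, LOSO ROIs, the searchlight RSA
and the full pipeline, each printing the numbers it computes.

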