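# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `valmux`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Task model and variables

The simulated paradigm crosses four outcome categories (monetary gain,
monetary loss, pleasant face, electric shock) with four magnitude levels.
A session is `n_blocks × trials_per_block` trials (default 4 × 24 = 96, six
repeats per condition), each 12 s long — a 6 s cue (anticipation) period
followed by a 6 s outcome period — separated by inter-trial intervals drawn
uniformly from 10–12 s and snapped to the 2 s TR grid. One third of trials
(`actualized_fraction`, rounded per condition cell) deliver their outcome;
all analyses of anticipation use **non-actualized cues only**, so outcome
responses cannot contaminate the cue-period estimates.

Per trial, **value** is the cue-period pleasantness rating (1–9) and
**saliency** is the squared deviation of the rating from the neutral point
5. Saliency is therefore in [0, 16], zero exactly at a neutral rating, and
invariant under the reflection r → 10 − r.

## Synthetic ratings

Ratings come from a latent linear-in-level model per category:
latent = 5 + slope(category)·level + subject intercept + noise, rounded to
the nearest integer and clipped to 1–9. Defaults: slopes +1 for gain/face
and −1 for loss/shock (opposing monotone trends for rewards vs
punishments), subject-intercept SD 0.3, latent noise SD 0.5, missingness 0.
With all noise at zero the construction is exact: a +1 slope maps levels
1–4 to ratings 6–9. Clipping mildly compresses the extreme cells; the
behavioral ANOVA sees this as a small nonlinearity, which is realistic for
bounded scales.

## Forward model for BOLD

Injected effects (`EffectSpec`) live in declared ROIs and enter the series
as 6 s cue-period boxcars convolved with a canonical double-gamma HRF
(response gamma peaking at 6 s, undershoot gamma at 16 s,
peak:undershoot = 6, unit integral; all four numbers are parameters).
Per-trial modulators: the rating for `value_linear`, (rating − 5)² for
`saliency_quadratic`, 1 for `mean_offset`; `category_pattern` adds a fixed
zero-mean, unit-norm voxel pattern per category. Effects are injected on
non-actualized, rated cues only — exactly the events the analysis GLM
models parametrically — so the GLM nests the forward model and noiseless
betas equal injected amplitudes to numerical precision (verified to 1e−6
relative in the tests).

Noise is AR(1) in time (default lag-1 correlation 0.3), spatially smoothed
Gaussian (default FWHM 4 mm on 3 × 3 × 4 mm voxels), rescaled to marginal
SD `sigma` (default 1, the unit in which all amplitudes are stated).
Physiological noise, motion, field inhomogeneity and multi-run effects are
not modeled.

A second pathway (`generate_condition_betas`) emits the 16 condition beta
volumes directly — the expected output of the 16-condition GLM plus
spatially smoothed beta noise — which is what the RSA/PCA null and recovery
studies use; it removes first-level GLM runtime from experiments that do
not test the GLM itself.

Category patterns are drawn independently per subject by default (an
idiosyncratic code: group-level *fixed-effect* category tests are blind to
it, which is what makes the "no univariate category contrast" control
meaningful). `shared_pattern=True` draws one pattern set for all subjects
(a population-consistent code), which is the regime in which group-level
mixed-model category tests are informative; the PCA multiplexing scenario
uses this. `orthogonalize_to_value=True` residualizes the per-condition
pattern weights (category indicators) against the subject's condition mean
ratings. Without it, value and category are inherently correlated at the
condition level — rewards are rated high — and any condition-level
decomposition (PCA included) mixes the two codes into the same component;
the orthogonalized scenario is the controlled experiment in which the codes
are separable in principle, so separation failures indict the analysis,
not the stimulus design.

## Preprocessing and GLMs

Per voxel: linear detrend and a discrete-cosine high-pass removing
frequencies at or below three cycles per scan (implemented as regression on
an orthonormalized drift basis, exactly nested in OLS), optional Gaussian
smoothing (6 mm FWHM for the univariate pathway, none for pattern
analyses), then a z-transform (mean 0, SD 1 per voxel), so betas are on a
z-score scale. Constant voxels are flagged invalid.

The main design has eight task regressors — non-actualized cue (binary,
with demeaned value and saliency parametric modulators), actualized cue,
actualized outcome (binary, with demeaned outcome value/saliency
modulators), non-actualized outcome — plus a missed-trial regressor when
ratings are missing, optional motion nuisances, and an intercept.
Demeaning makes the unconvolved modulator weights sum to zero per subject
(decorrelating them from the cue binary at the event level); value and
saliency enter jointly and are *not* serially orthogonalized — shared
variance is split by OLS. Other variants: one binary cue regressor per
observed rating level (`rating9`), per condition (`cond16`), or per
category with value/saliency covariates (`category`). Regressors are built
on a 10× oversampled grid and decimated at frame times. Fitting is
voxelwise OLS via the pseudoinverse, with a QR-based rank check that names
dependent columns. No prewhitening is applied at the first level; the
group stage is a random-effects one-sample t (df = n − 1), which is valid
under first-level autocorrelation.

## Cluster-extent FWE

Map smoothness is estimated per axis from the variance of spatial first
differences of per-voxel-normalized residuals: for a Gaussian kernel of SD
s, neighbours at spacing d correlate as exp(−d²/4s²), so
FWHM = d·√(−2 ln 2 / ln ρ) with ρ = 1 − var(diff)/2. Group-stage
smoothness uses the across-subject residual maps (subject map minus group
mean). The Monte-Carlo threshold simulates Gaussian fields at that
smoothness inside the mask, binarizes at the z equivalent of the per-voxel
p (two-tailed for t maps, one-tailed for the signed-rank z maps), records
each field's maximum 6-connected cluster, and returns the smallest k with
P(max ≥ k) ≤ α. Connectivity is switchable to 18/26. Surviving clusters
report size, unweighted center of gravity, mean and peak statistic.

## LOSO ROIs

For each held-out subject, the other n − 1 subjects' contrast maps are
thresholded (per-voxel p < 0.005, cluster FWE 0.05); the surviving cluster
with maximal overlap with a user-supplied seed mask is selected, and a
sphere (default radius 5 mm, membership by voxel-center Euclidean distance
in mm) at its center of gravity becomes that subject's ROI. Folds with no
surviving overlapping cluster are reported undefined and dropped from ROI
statistics. Independence from the held-out subject is tested by
perturbation. One smoothness estimate is computed per fold.

## Searchlight RSA

Patterns are the in-mask voxels of the 3×3×3 cube around each in-mask
center (≥ 14 of 27 required; configurable). The neural RDM uses the
Pearson correlational distance 1 − corr with mean-centering, hence
invariance to shared positive scaling and to offsets applied uniformly
across voxels — the property that makes RSA blind to mean-activation
(univariate) signals. One caveat is documented and exercised in the tests:
at the *spatial boundary* of a bounded univariate effect, the profile's
gradient is itself a pattern, and searchlights straddling the edge can pick
it up; the scale-invariance guarantee applies where the profile is locally
uniform. Model–neural agreement is Spearman rho over the 120
lower-triangle entries with average ranks for ties (the categorical models
are heavily tied).

Group inference is a one-sided Wilcoxon signed-rank test of rho > 0 per
center: zeros dropped, midranks for ties, z from the normal approximation
(with tie correction), and the one-sided p from full enumeration of the
2ⁿ sign assignments whenever there are no ties or zeros and n ≤ 30 (e.g.,
p = 2⁻¹⁷ ≈ 7.6 × 10⁻⁶ for 17 concordant subjects), otherwise from the
normal approximation. Two conservatisms are inherent and measured by the
null-calibration test: the discrete W⁺ distribution at n = 17 attains
0.00467 rather than 0.005, and the null distribution of Spearman rho
against the category model is slightly right-skewed (negative median), so
the across-center rate of p < 0.005 sits near 0.003–0.004 — within the
Monte-Carlo band around nominal at this grid size, and on the conservative
side, never anticonservative. Because neighbouring searchlights share
voxels, a single map's rate is overdispersed relative to a binomial count;
the calibration test averages several independent cohorts for a stable
estimate.

## PCA multiplexing

Per subject and ROI, the 16 × m condition-by-voxel beta matrix is
decomposed by covariance PCA (per-voxel centering across conditions, no
variance scaling — chosen so a uniform activation signal yields a
mean-activity-like first component). Components are sign-fixed by making
the largest-magnitude loading positive: for one-signed components this
coincides with requiring a non-negative mean loading, but it remains
deterministic and stable for mixed-sign pattern components, whose mean
loading is near zero — an unstable sign there would scramble score
orientation across subjects and erase group-level effects. Scores of the
first three components are regressed on value, saliency and three category
dummies (shock as reference) with a subject random intercept (16
observations per subject cannot support richer random structure); reported
alongside the per-term tests are a value-minus-saliency contrast and a
joint Wald test of the three category dummies — the joint test is the
appropriate "category effect" summary, avoiding the threefold per-dummy
type-I inflation. Singular mixed fits fall back to a subject-demeaned
fixed-effects regression, flagged in the output.

Scenario amplitudes follow an eigenvalue-separation argument: for a 16 × m
noise matrix the largest noise eigenvalue is ≈ (√16 + √m)²σ²; the category
components' eigenvalues must clear that edge, and the value component's
eigenvalue must clear the category components' (leakage between correlated
or close components scales with the eigenvalue ratio). The defaults
(uniform value amplitude 1.0 per rating point, pattern norm 18, m = 216,
σ = 1) satisfy both with margin.

## Behavioral ANOVA

Per-subject cell means over the 2 (valence) × 2 (modality) × 4 (magnitude)
design are screened per cell across subjects with the boxplot rule (strictly
beyond 1.5 IQR from the quartiles; zero-IQR cells flag nothing). Flagged
cells are mean-imputed from the remaining subjects by default (listwise
deletion is available; the handling of the unbalanced design after removal
is genuinely underdetermined, so both are offered). Each effect's F comes
from orthonormalized contrast scores Z (Kronecker products of ±1/√2
two-level contrasts and orthonormal polynomial contrasts for magnitude):
F = n·Z̄′Z̄/q over tr(S)/q on (q, q(n−1)) df, with S the sample covariance
of Z. For q > 1 effects, Mauchly's W = det(S)/(tr(S)/q)^q is tested by its
chi-square approximation and, when its p < 0.05, the Greenhouse–Geisser
epsilon tr(S)²/(q·ΣS²) multiplies both df — the conditional-correction
reporting style. The magnitude effect and epsilon are cross-checked
against pingouin's one-way repeated-measures ANOVA in the tests.

## Study conditions and problem sizes

`scenarios` pins the conditions used by the validation suite: 18 subjects
for behavior; 12 subjects on a 24³ grid for univariate recovery with
amplitudes calibrated once so the single-subject voxel t of the value
modulator is ≈ 3 (value 0.04 per rating point, saliency 0.02 per squared
point, at σ = 1 with 6 mm analysis smoothing — the calibration is a
pre-registered property of the scenario, not a per-run fit); 17 subjects
on a 20³ grid, betas-only, for the RSA scenarios (pattern norm 9 over a
6³ ROI; the rank-1 value profile covers the whole volume so that every
searchlight sees a locally uniform profile — see the boundary caveat
above); 17 subjects, 12³ grid, 6³ ROI for PCA multiplexing. Monte-Carlo
cluster thresholds use 500 simulated fields in the validation runs (1000
where a threshold itself is the quantity under test); detection and
calibration rates use 30–50 cohorts, sizes chosen so the full suite runs
in minutes on one CPU. The ROI-statistics round trips (external-mask
effect tests, nine-level rating profiles) run on compact 32-trial,
6–8-subject time-series cohorts — enough for the large injected effects
they check, while keeping first-level GLM runtime negligible.

## What passing tests do and do not show

The generator shares its HRF, its event timing and its noise family with
the analysis; recovery results therefore validate the *inference machinery*
(identifiability, calibration, selectivity), not robustness to HRF
mismatch, motion, physiological noise, or registration error. Real-data
idiosyncrasies — unequal condition counts after exclusions, non-Gaussian
noise, anatomical variability in ROI placement — are outside the synthetic
model, except for missing ratings, which are supported end to end.

## Known limitations

- First-level OLS without prewhitening (group inference remains valid;
  single-subject t values are approximate under AR(1) noise).
- The smoothness estimator assumes a Gaussian autocorrelation; heavy-tailed
  spatial correlation would bias the cluster threshold.
- The signed-rank group test is mildly conservative (discreteness and null
  skew, quantified above).
- Mixed models use a random intercept only; subject-specific slopes are
  absorbed into the residual.
- No anatomical atlases: LOSO target matching uses user-supplied seed
  masks; cluster tables carry coordinates, not labels.
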