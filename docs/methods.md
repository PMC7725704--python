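# Methods

`petsim` reimplements, on fully synthetic data, a simulation study of how
errors in MR-based attenuation correction (MRAC) of brain FDG-PET propagate
into an automated Alzheimer's-disease discrimination statistic (the
"PET score"). The pipeline has four stages: phantom generation, scoring
against an age-regressed normal database, multiplicative error injection, and
diagnostic-accuracy evaluation.

## The scoring statistic

Each subject volume is (optionally) smoothed with a separable Gaussian kernel
(default FWHM 12 mm isotropic; sigma = FWHM / (2 sqrt(2 ln 2)) converted to
voxels) and intensity-normalized by dividing by its mean over a
preserved-uptake mask — a region whose metabolism is typically spared in AD —
so that any global multiplicative scaling cancels exactly.

A reference database of healthy controls supplies per-voxel ordinary
least-squares parameters of normalized uptake on age: intercept `a_v`, slope
`b_v`, and residual SD `s_v` (denominator n − 2), together with `n`, the mean
control age `ā`, and `S_xx = Σ(age − ā)²`. A subject of age `x` is compared
voxelwise with its age-specific prediction using the single-new-observation
prediction standard error:

    t_v = (a_v + b_v·x − u_v) / ( s_v · sqrt(1 + 1/n + (x − ā)²/S_xx) )

with the sign convention expected − observed, so hypometabolism gives
positive t. Outside the brain mask t is 0.

The AD t-sum is the plain sum of `t_v` over the AD-pattern mask — negative
values included, no thresholding (the commercial tool's tie-breaking here is
not public; summation without thresholding is the simplest defensible
reading, and it makes the score an odd-symmetric function of the deviation
field). The PET score is

    PET score = log2(AD t-sum / K + 1),   K = 11089,

where K is the published 95% prediction limit of the AD t-sum, so PET
score = 1 marks that limit, score 0 corresponds to t-sum 0, and the map is
strictly increasing.

Numerical choices: the residual SD is floored at `s_floor` (default
1e-6 × mean normalized uptake over the brain) so that noise-free synthetic
databases do not divide by zero; smoothing uses zero-padded convolution with
all statistics subsequently restricted to the brain mask; normalization is
applied after smoothing.

## Phantoms

All volumes live on one template grid (default 91×109×91 at 2 mm isotropic;
tests and the analysis scripts use 32³ for speed — problem sizes are a
package choice, stated per script). Masks are deterministic geometry: the
brain is a centered ellipsoid with semiaxes at 42% of each grid extent; the
AD-pattern mask is its posterior-superior sector (a proxy for
temporoparietal/posterior-cingulate hypometabolism); the preserved-uptake
mask is the disjoint anterior-inferior sector.

A control phantom has uptake `base_uptake` (default 100 a.u.) inside the
brain, zero outside, plus a linear age effect `age_slope_per_year` (default
−0.5 a.u./y, i.e. −0.5%/y — the magnitude of age-related decline reported
for association cortex) inside the age-sensitive region, defined as brain
minus the preserved mask so the normalization reference stays age-flat. AD
phantoms additionally lose a fixed fraction `ad_severity` (default 0.15,
within the 10–25% deficits reported for AD temporoparietal cortex) inside the
AD-pattern mask. Between-subject variability is voxelwise-independent
lognormal noise with unit mean and SD `subject_noise_sd` (default 0.10);
lognormal rather than additive Gaussian keeps uptake nonnegative. Ages are
uniform on 55–90 y. Every generator is a pure function of (params, seed).

## Error fields

A multiplicative attenuation-error field emulates the ratio of an
MRAC-corrected PET volume to its CT-corrected counterpart:

    field = 1 + bias·w + sd·w·G   inside the brain, exactly 1 outside,

where `G` is Gaussian-smoothed white noise renormalized to zero mean and unit
variance over the brain (correlation length 10 mm), and
`w = 1 + skull_weight·shell` (default skull_weight 2) up-weights the 3-voxel
shell inside the brain boundary, where MR-based attenuation maps err most
(bone misclassification). Two regimes are configured: ZTE-like
(bias −0.02, sd 0.02) and atlas-like (bias −0.02, sd 0.05). The shared −2%
bias and the 2.5× variability ratio reproduce the qualitative findings of
MRAC validation studies — both methods slightly underestimate on average,
and zero-echo-time bone imaging mainly reduces the *variability* of the
error; the values are round numbers in the reported few-percent range, not
fits.

Measured error maps (ratio of two PET volumes) are supported through
`compute_error_map` (epsilon-guarded division, ≤1% near-zero denominators
tolerated) and `condition_error_map` (mask-normalized smoothing: field×mask
and mask are smoothed separately and divided, so brain-edge ratios are not
diluted toward the outside fill; outside brain reset to 1). Synthetic fields
are generated smooth and brain-masked already and enter the cross product as
conditioned maps. Injection is a plain voxelwise product with no
re-smoothing, enforced by a `conditioned` flag.

A spatially **uniform** multiplicative error changes the normalization
factor by the same amount and therefore changes no PET score; only spatially
structured error propagates. This cancellation is asserted by test.

## Evaluation

Per-regime summaries of signed and absolute PET-score differences
(simulated − original); paired t-test (n−1 df) between regimes' absolute
errors; per-subject means across error maps; OLS regression of simulated
means on original scores with R²; Bland-Altman bias and limits of agreement
(mean ± 1.96 sample SD, fixed multiplier); fixed-cutoff classification
(positive iff score ≥ cutoff) with Wilson 95% CIs; empirical ROC with
trapezoidal AUC (equals pairwise concordance with ties counted ½), seeded
class-stratified percentile-bootstrap AUC CI (default 2000 reps), and
Youden-index cutoff (argmax sensitivity + specificity − 1, lowest threshold
on ties). Rows sharing a subject are pooled as independent by default; a
subject-level cluster bootstrap is available (`bootstrap_auc_ci(...,
subject_ids=...)`) as the conservative alternative.

## What the phantoms do and do not show

They exercise every pipeline contract: normalization cancellation, regression
recovery, t-map algebra, cross-product bookkeeping, and the directionality
that a lower-variance error regime yields smaller absolute score error and
tighter agreement with the original scores. They are not anatomically
realistic: no gray/white parcellation, no attenuation physics, and —
because the subject noise is voxelwise independent — the AD t-sum averages
it over thousands of voxels, so NC and AD phantoms separate almost perfectly
(AUC ≈ 1 for unperturbed scores) in contrast to the overlap of real
cohorts. For the same reason the score axis is compressed at small grid
sizes (the AD mask has ~2.5k voxels at 32³ against the much larger set
behind K = 11089), so the conventional fixed cutoff of PET score = 1 sits
above the synthetic AD distribution; Youden-derived cutoffs are the
meaningful operating points on phantoms. Passing tests therefore validate
the mechanics and directions of the method, not its clinical accuracy
figures.

## Degenerate inputs and tie-breaks

Grid mismatches raise everywhere rather than broadcast; masks must satisfy
AD ⊆ brain, preserved ⊆ brain, AD ∩ preserved = ∅; all-equal control ages
raise ("degenerate age design"); a nonpositive normalization mean raises; a
t-sum at or below −K raises (log argument ≤ 0); scores exactly at a cutoff
classify positive; Youden ties resolve to the lowest threshold; error-field
parameters producing nonpositive values on >1% of brain voxels before the
0.1 clip raise as misconfiguration.
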