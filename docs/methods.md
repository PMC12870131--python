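# Methods

This note documents the models implemented in `fixtract`, their assumptions,
the defaults that matter, and the choices made where the design was open.

## Fixel substrate

A fixel field stores, per voxel on a regular grid (default 2 mm isotropic),
up to K = 2 fibre populations — unit orientation `u_k`, volume fraction
`f_k ≥ 0`, tensor metrics FA (unitless), AD, RD, MD (mm²/s) — plus an
isotropic fraction `f_iso` with `f₁ + f₂ + f_iso = 1`.  `f₂ = 0` marks
single-population voxels.  The isotropic compartment models free water
(diffusivity default 3×10⁻³ mm²/s, free water at body temperature).
Fitting this substrate from raw diffusion signal is out of scope: fields
are pipeline inputs, produced here by the synthetic generator.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not anatomical
realism:

* **Geometry.**  Bundles are tubes of radius r (default ~4 mm) around
  polyline centerlines; a voxel belongs to a bundle when its centre is
  within r of the polyline (exact point-to-segment distance).  At most two
  bundles may overlap in a voxel; a third is rejected with a diagnostic.
  Metrics are generated jointly from an axially symmetric tensor
  (λ∥, λ⊥) — default coherent-WM values (1.7, 0.4)×10⁻³ mm²/s — so
  MD = (AD + 2·RD)/3 and FA = (λ∥−λ⊥)/√(λ∥²+2λ⊥²) hold by construction.
* **Cohort.**  Defaults follow the study conditions: ~40 patients and ~20
  controls, two sessions (E1 admission, E2 after ~18 days), patient ages
  ~N(47.6, 10.5²) years, controls ~N(51.3, 15.1²), sex ratios 42:11 and
  13:7, daily alcohol consumption ~N(18.9, 11.7²) units for men and
  N(11.36, 7.67²) for women (1 unit = 10 g ethanol), floored at 0.5.
* **Effects.**  Planted group/session differences on one bundle metric,
  additive or multiplicative, whole-tract or restricted to arc-length
  octants (1–8).  The defaults mirror the reported pattern: a diffuse AD
  and FA decrease along the "cingulum" tube, a localized AD decrease in
  sections 4–5 of the "uncinate", and an unaffected callosal tube as
  negative control.  Every applied effect is written to a machine-readable
  truth ledger for recovery tests.
* **Noise.**  Independent Gaussian noise per metric per fixel
  (sd defaults: FA 0.02, diffusivities 5×10⁻⁵ mm²/s), scaled by
  `1 + slope/CNR` (slope 5, CNR ~N(20, 4²)) — any monotone contamination
  satisfies the residualization design; linear was chosen for analytic
  tractability.  A stable between-subject offset per metric (FA 0.015,
  diffusivities 4×10⁻⁵) models biology; session noise is correlated within
  subject (default ρ = 0.5 — a free parameter, not an estimate, since no
  within-subject variance components are reported for this design).
  Physical ranges are enforced by clipping, which breaks the exact tensor
  consistency of noisy voxels, as measurement noise does in practice.
* **Clinical scores.**  BDI/OCDS/SAI are linear in group, session and
  mean-centred tract summaries plus Gaussian residuals; default planted
  signs: lower FA and higher RD on designated tracts predict higher
  depression.  Scores are clipped to instrument ranges (BDI 0–63,
  SAI 20–80, OCDS ≥ 0) in cohort generation; the model-recovery study
  disables clipping because floor effects at the control-group E2 mean are
  outside the linear model it validates.

What passing tests do **not** show about real data: the generator has no
registration error, no partial-volume gradients at tissue boundaries, no
spatially correlated noise, shares one grid and one anatomy across
subjects, and uses geometric tubes rather than anatomical tracts.  Results
validate the machinery, not effect sizes in patients.

## Weighted maps and cluster detection

`wM = Σf_k·M_k / Σf_k`; voxels with no anisotropic mass are NaN and excluded
from all downstream statistics.  The group comparison is an OLS of wM on
{intercept, group, age} per voxel (with one binary factor plus a covariate
the group F equals t², i.e. an age-corrected single-factor ANOVA), two-sided
p < 10⁻⁴ cluster-forming threshold.  Zero-residual-variance voxels report a
capped |t| = 10⁶ rather than infinity.

Residual smoothness is estimated from lag-1 autocorrelations of the
residual maps, expressed as the FWHM of the Gaussian kernel that reproduces
that autocorrelation on white noise (ρ(d) = exp(−d²/4s²)), floored at the
voxel size.  Cluster-size thresholds come from two backends:

* **Gaussian Monte Carlo** (default): ≥200 null fields smoothed to the
  estimated FWHM, thresholded two-sided, maximal 26-connected cluster size
  recorded; the threshold is the smallest size with exceedance probability
  ≤ 0.05.  This calibration is exact for its own null model but measurably
  conservative when applied to t-maps at moderate degrees of freedom
  (df ≈ 37): the t-field's excursions are smaller than a Gaussian field's
  at the same voxelwise rate, so true familywise error falls below nominal.
* **Group-label permutation**: the GLM is re-fit under permuted group
  labels of the actual cohort and the max-cluster-size distribution taken
  from the permuted t-maps; this matches the t-field geometry exactly and
  is the backend of choice when calibration cost is acceptable.

Connectivity (26 default, 6/18 available), sign-separated components
(positive and negative t clusters labeled independently, since cluster
tables report signed t), unweighted mass centre rounded to the nearest
voxel and reported in world mm, modal atlas label with peak-voxel
tie-breaking, background-majority clusters labeled "unlabeled".
Per-metric minimum cluster sizes are recomputed per cohort — they depend on
that cohort's smoothness and are not portable constants.

## Tracking

A deterministic best-aligned-fixel tracker stands in for probabilistic
fODF tractography (the downstream analysis consumes only geometry): seeds
uniform within the seed ROI, bidirectional Euler integration at 1 mm steps,
at each step following the antipodally symmetrized fixel best aligned with
the incoming direction; stopping at anisotropic fraction < 0.1 (the nearest
fixel-field analogue of an fODF amplitude cutoff), per-step turns > 15°
(bounding the curvature radius to ≈ 3.8 mm at 1 mm steps), or the grid
edge.  Accepted streamlines satisfy 10–200 mm length bounds, traverse every
intermediary ROI and satisfy termination ROIs (pass-through by default;
endpoint-constrained per ROI on request), up to 2000 per tract.

Cleaning removes streamlines with isolated segments: an unnormalized
Gaussian kernel sum (bandwidth 1 mm) over all streamline points, subsampled
to ≤ 1 point/mm; a streamline is dropped when any of its points has density
below 5× the single-point kernel peak.  The point-based reading of
"segment density" is adopted.  The filter iterates to a fixed point so
survivors are evaluated on the cleaned set; a lone 1 mm-spaced streamline
has own-density ≈ 2.5 and is removed at the default threshold.

## Tractometry

Angular weight = normalized cos² of the acute angle between the voxel's
mean streamline direction and each fixel (antipodally invariant, exactly
zero at 90°, uniform in the all-orthogonal degenerate case); the fixel
fraction does not enter the attribution weight (a combined f·cos² mode
exists but is off by default), and a winner-take-all `closest_fixel` scheme
is available.  The voxel's mean direction is the leading eigenvector of the
dyadic sum of central-difference segment directions observed in it, so
every point in a voxel shares one value and point averages equal
density-weighted voxel averages — this makes the 8-section profile conserve
the whole-tract mean exactly (weights = per-section point counts).

The mean trajectory resamples each streamline to equidistant nodes, flips
streamlines whose endpoints oppose the reference ordering, and averages
node-wise; points join the section of their nearest node (projection onto
curved trajectories is ill-posed).  CNR residualization fits
`M = β₀ + β_CNR·X_CNR` by OLS per tract × metric, pooled over groups and
sessions (the finest grouping the design supports without emptying cells),
and analyses `M_res = M − M̂`; by construction mean(M_res) = 0 and
corr(M_res, X_CNR) = 0.

## Statistics

Welch's t (Satterthwaite df) with a p = 1 convention for equal-constant
degenerate inputs so simulation loops stay total; Bonferroni gates at
α/m with the family defined per metric across tracts (config-exposed).
Correlations are Pearson when both variables pass Shapiro–Wilk at α = 0.05,
Spearman otherwise; BH-FDR reports each p-value's rank critical value
i·q/m alongside the step-up flags.  The longitudinal model is OLS on
{intercept, group, time} main effects (no interaction).  The depression
model regresses BDI on group (controls coded 1, so the coefficient is
negative when patients score higher), time, and mean-centred tract metrics,
with a subject random intercept fit by REML; singular or failed mixed fits
fall back to fixed effects with a warning flag.  VIFs are computed on the
fixed design with the intercept in the auxiliary regressions; predictors
with VIF ≥ 10 are flagged.  Consumption regressions relate units/day to E1
values and E1→E2 changes per tract × metric, Bonferroni-gated per target
family.

## Problem sizes and numerical choices

The validation studies run at desk scale: weighted-map identities on 10⁴
random voxels; crossing recovery on a 31×31×11 grid with 50 streamlines;
lesion localization over 100 cohorts of 20+20 subjects (44×13×23 grid,
effect = 3× the voxel noise sd, geometry tracked once on the shared
template since noise does not move orientations); familywise error over
200 null datasets on a 40³ grid at 6 mm smoothness (Monte-Carlo backend
validated on its Gaussian null model, permutation backend on full GLM
cohorts — both must land in the 95% binomial CI of 0.05); clinical sign
recovery over 100 cohorts via the reduced (image-free) summary generator.
Tolerances: exact identities at 1e-12, geometric recoveries at 1e-9,
OLS contracts at 1e-10.  Seeds flow from a single root through
`numpy.random.SeedSequence`; identical configs reproduce identical artifact
hashes.

## Known limitations

Deterministic tracking underestimates spatial dispersion relative to
probabilistic methods; the corpus-callosum arc-length subdivision is a
coordinate partition, not a fibre-topography atlas; the Gaussian Monte-Carlo
cluster backend is conservative on t-maps (use the permutation backend when
exact familywise control matters); mixed-model fallback to OLS changes the
standard errors, and is reported in the result's method tag.
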