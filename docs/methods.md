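# Methods

`sctqa` implements the quantitative validation chain used when a synthetic
CT (sCT, an HU-valued volume derived from MRI) is assessed against a
conventional planning CT (pCT) for MR-only radiotherapy planning:
data conditioning, HU similarity metrics, dose–volume-histogram (DVH)
comparison of plans recalculated on each CT, 3D gamma analysis of the two
dose distributions, and the statistical tests linking image similarity to
dosimetric agreement.  Because clinical CT/sCT/dose data cannot ship with
the package, a digital head phantom generates paired volumes with a
controlled conversion-error model, so every stage is exercised end to end
at desk scale.

## Grid model

All volumes live on axis-aligned regular grids: `world = origin +
index * spacing`, 0-based indices, origin at the **center** of voxel
(0,0,0).  NIfTI/NRRD affines are normalised to this convention at load
time (axis permutations and flips only; oblique acquisitions are
rejected rather than silently resampled).  Interpolation is trilinear and
exact at voxel centers.  Displacement fields use pull (backward) warping:
the displacement stored at a reference voxel is added to that voxel's
world position to find the sampling location in the moving volume.
Resampling fills out-of-extent samples with −1000 HU for CT (air) and 0 Gy
for dose, and clamps CT below at −1000 HU.  Grid equality is tested to
1e-6 mm to survive text round-tripping of headers.

## Preprocessing

`zero_outside_body` removes couch/immobilisation signal by assigning a
constant to every voxel outside the BODY contour.  The default constant is
0 HU (water-equivalent), the convention of treatment-planning exports; an
air value (−1000 HU) is available via `outside_value` because zero-filling
is a debatable choice for a quantity later averaged over the full grid.
`align_pair` resamples the synthetic CT onto the planning grid through an
optional externally estimated displacement field; estimating that field is
out of scope — the package consumes registrations, it does not produce
them.

## HU image-quality metrics

Over a stated ROI (full grid by default; BODY-restricted optionally, since
ROI choice biases MAE downward when large air regions are included):

- ME   = mean(sCT − pCT)            (signed; >0 ⇒ sCT reads high)
- MAE  = mean|sCT − pCT|
- RMSE = √mean (sCT − pCT)²
- PSNR = 10·log₁₀(peak² / MSE), peak defaulting to max sCT over the ROI;
  a fixed peak (3000 HU) is used by the cohort pipeline so PSNR ranks
  cases by MSE alone rather than by each case's own maximum, which
  otherwise drifts upward with bias/noise and breaks cross-case
  comparability.
- SSIM = (2μₛμₚ + C1)(2σₛₚ + C2) / ((μₛ² + μₚ² + C1)(σₛ² + σₚ² + C2)),
  C1 = (k₁L)², C2 = (k₂L)², k₁ = 0.01, k₂ = 0.03, L = observed dynamic
  range unless fixed.

SSIM is offered **globally** (one evaluation from ROI-wide moments — one
scalar per case, the default) and **windowed** (mean of local 7³-window
SSIM via scikit-image).  An optional min–max normalisation of both images
to [0,1] before PSNR/SSIM is provided; note that raw SSIM is *not*
invariant to adding a common constant to both images (the luminance term
depends on absolute means) — the normalisation switch is what makes it so,
and the property is tested in that form.  Identical inputs yield zero MSE;
PSNR then returns `inf` as an explicit "identical inputs" sentinel.

Always true, and enforced by property tests: RMSE ≥ MAE ≥ |ME|; ME is
antisymmetric under swapping the pair, MAE/RMSE symmetric; on a bias-only
phantom pair ME equals the injected bias exactly.

## DVH metrics

Cumulative DVHs use voxel-center membership (no partial-volume weighting;
structure masks come rasterised either from RTSTRUCT contours via even-odd
polygon fill or from the phantom) with a 0.01 Gy default bin width.
Reported metrics: D-mean, D-max (single maximum voxel dose, not a
small-volume surrogate), and V_x% — the percent of structure volume
receiving at least x% of the prescription (defaults 93%, 100%, 110%).
Differences between the plan on the planning CT (reference) and on the
synthetic CT (evaluated) are reported absolutely (evaluated − reference)
and as a percentage of the reference; a reference of zero (e.g. V110% = 0
on both plans) flags the relative entry "NA" instead of fabricating a
number.

## 3D gamma analysis

For every reference voxel above the low-dose threshold (default 10% of the
normalisation dose),

γ(r_R) = min over r_E of √( |r_E − r_R|²/δr² + ΔD(r_R, r_E)²/δD² ),

with δr the distance-to-agreement criterion (mm) and δD the
dose-difference criterion, expressed as a percent of the maximum reference
dose (global normalisation, the default) or of the local reference dose.
A voxel passes when γ ≤ 1; the global passing rate is reported against the
conventional 95% clinical acceptance level.  Criteria 3%/3 mm, 2%/2 mm and
1%/1 mm with the 10% threshold are the package-wide standard set.

Numerical choices:

- The evaluated dose is sampled trilinearly on a cubic offset lattice of
  pitch `interp_step_fraction · δr` (default δr/10), visited in shells of
  increasing distance; a voxel stops participating once the spatial term
  alone exceeds its current minimum, and the search is bounded at
  `search_radius_factor · δr` (default 3δr).
- An optional `max_gamma` cap skips offsets whose spatial term alone
  exceeds the cap; values above the cap are then upper bounds, while
  pass/fail at γ ≤ 1 is exact for any cap ≥ 1.  The cohort pipeline uses
  cap 2 for speed.
- Ties in the minimisation are resolved by value only.
- Samples falling outside the evaluated extent are skipped, not imputed.
- γ(A,B) ≠ γ(B,A) in general; the package follows the convention
  reference = planning-CT dose, evaluated = synthetic-CT dose.

`gamma_brute_force` is an independent oracle for grids up to ~25³ analysed
voxels: per voxel it enumerates a dense offset ball (pitch δr/20) whose
radius is that voxel's zero-offset gamma — an exact bound, because beyond
it the spatial term alone already exceeds a known candidate — so the
result equals unrestricted exhaustive enumeration at that sampling
density.  Equivalence tests compare the two engines at a matched lattice
pitch so the comparison isolates the search logic (shell pruning, early
termination, radius cap) rather than sampling-density differences; the
residual discretisation error of a pitch-p lattice is O(p/δr) and is the
reason per-voxel agreement is asserted at 0.02 rather than 0.

## Statistics

Thin validated wrappers over scipy.stats: Shapiro–Wilk normality
screening (3 ≤ n ≤ 5000), two-sided independent-sample t-tests between
technique groups, two-sided Wilcoxon signed-rank tests for paired
planning-vs-synthetic DVH metrics (zero differences dropped; an all-zero
difference vector is flagged "not applicable" rather than tested; exact
enumeration up to n = 25 nonzero pairs, tie-corrected normal approximation
beyond), Spearman rank correlation with average-rank ties (n ≥ 3), and
Bonferroni correction min(1, p·m) with the family size m defaulting to one
family per table of comparisons (the exact family sizes are configuration,
not doctrine).  Significance is declared at adjusted p < 0.05.  A seeded
calibration harness (2000 null replicates at n = 15 per group) verifies
the empirical type-I error of both tests stays within 5% ± 1.5%.

## Digital head phantom

The phantom emulates the statistical structure the pipeline assumes, not
anatomy per se:

- **Geometry** — background air at −1000 HU, an ellipsoidal soft-tissue
  head (default radii 70×85×75 mm at 40 HU), an ellipsoidal skull shell
  (8 mm, 900 HU), sinus-like air cavities, a spherical PTV and spherical
  OARs ("brainstem", "lens") at configurable offsets.  The BODY mask is
  every voxel above background air + 50 HU.
- **Conversion-error model** — the knobs that turn the planning CT into a
  "synthetic CT": a global HU bias (the systematic offset synthetic CTs
  show in soft tissue; cohort default ≈ 25 HU), i.i.d. Gaussian HU noise
  (20–45 HU), bone-interface misclassification as dilation/erosion of the
  thresholded (>200 HU) bone compartment with a spherical structuring
  element (sub-half-voxel radii are a no-op rather than being inflated to
  a full voxel), a facial-contour shift along one axis, and an optional
  spherical signal-void artifact.  Everything outside BODY is untouched.
- **Toy dose engine** — a parallel beam attenuated exponentially along an
  axis: dose(depth) = D₀·exp(−μ·radiological depth), with radiological
  depth the midpoint-rule integral of relative density
  ρ(HU) = max(0, 1 + HU/1000) from the body surface, μ = 0.004/mm at
  water density, and dose 0 outside BODY.  This is an explicit toy, not a
  clinical dose algorithm; it preserves the single property the QA chain
  must detect — HU errors along the beam path perturb the dose — and its
  closed forms (vacuum transparency, water exponential, ratio under a
  uniform HU offset) make it testable.  The prescription defaults to the
  mean reference dose in the PTV, mimicking a coverage-normalised plan.

All randomness flows through explicit integer seeds; identical
(spec, model, beam, seeds) reproduce bit-identical cases.

What the phantom does **not** emulate: realistic anatomy and tissue
heterogeneity, MR acquisition or any actual MR-to-CT conversion
algorithm, scatter/buildup/penumbra physics, immobilisation devices, or
registration error beyond a rigid contour shift.  Tests passing on the
phantom therefore validate the *pipeline arithmetic and its
sensitivities*, not the clinical performance of any synthetic-CT product.

## Problem sizes

Desk-scale defaults keep the full suite and the acceptance script
single-CPU friendly: cohort phantoms are 26×30×26 voxels at 6 mm,
gamma oracle-equivalence fixtures 10³ voxels at 3 mm, the noise-MAE
identity uses a ≥10⁶-voxel BODY at 1.2 mm, and the statistical
calibration runs 2000 replicates.  These sizes are the package's choices
for a reproducible demonstration; all of them are parameters, and scale up
unchanged.

## Known limitations

- Only axis-aligned geometries; oblique series must be reoriented first.
- The toy dose engine has no lateral transport; gamma results on phantom
  cohorts exercise the engine but do not predict clinical pass rates.
- Global-mode SSIM compresses a 3D comparison into one covariance ratio;
  windowed mode is preferable when spatial structure matters.
- The gamma engine assumes the evaluated dose is smooth at the δr/10
  sampling scale; pathological high-frequency dose grids would need a
  finer `interp_step_fraction`.
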