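# Methods

## Scope and model

`tractaging` implements classical single-tensor tractometry with a
longitudinal statistical layer, validated on synthetic phantoms. The
processing chain mirrors the workflow used by longitudinal aging studies of
subcortico-frontal white matter: diffusion tensor reconstruction and FA
mapping from DWI, whole-volume deterministic FACT tractography, extraction
of tracts of interest by intersection with labeled seed/target regions,
along-tract parameterization into 100 equidistant segments, and
per-connection change statistics across 2–3 examination waves.

Assumptions: a single rank-2 tensor per voxel (no crossing-fiber model),
monoexponential Stejskal–Tanner signal, magnitude (Rician) noise, and data
already co-registered in one space. Eddy-current correction, multimodal
registration, and anatomical segmentation are out of scope; label volumes
are consumed as input.

## Phantom cohorts

The synthetic-data module is the package's substitute for an unavailable
clinical cohort and is itself first-class, tested code. It emulates:

* **Acquisition**: 25 gradient directions at b = 1000 s/mm² plus five b = 0
  volumes. The real gradient table was not published; directions are a
  deterministic golden-spiral hemisphere sampling.
* **Geometry**: bundles are tubes of radius 4 mm around parametric
  centerlines. The default fixture has three bundles — straight, C-shaped
  arc, S-curve — in a 40×40×20 voxel grid at 2 mm isotropic, chosen to cover
  constant, curved, and inflected tangent fields (the cases that stress a
  deterministic tracker) at desk-scale cost. The rasterized tube is finite
  (no spherical end caps), so the FA support ends where the centerline
  ends. In-tube tensors are axially symmetric, `D = λ₂I + (λ₁−λ₂)ttᵀ`, with
  the principal eigenvector along the local tangent; the background is
  isotropic with the same trace.
* **Tissue**: trace fixed at 2.1×10⁻³ mm²/s (typical adult white matter);
  only anisotropy varies with "aging". The eigenvalue triple for a target
  FA f is the closed-form prolate inverse
  `λ₂ = λ₃ = (T/3)(1 − f/√(3−2f²))`, `λ₁ = T − 2λ₂`.
* **Longitudinal design**: 2 or 3 waves, inter-wave intervals drawn from
  N(3.6, 0.4²) years per subject, baseline age N(59, 7²) years, baseline
  bundle FA 0.45, and a per-subject true annual decline drawn once from
  N(1.5, 0.5²) %/yr. Decline is applied to the generative eigenvalues
  (FA at wave w is `FA₀·(1−r/100)^elapsed`), so noisy FA estimates scatter
  around a known truth. All waves share one grid: co-registered by
  construction.
* **Noise**: Rician via two Gaussian channels; SNR defined on the b0 signal,
  default 25. The emulated study reports no noise characteristics, so SNR
  is a free parameter of the phantom, not a reproduction of the study's
  noise floor. The simulated volumes carry a 2-voxel low-signal air border
  so that Otsu-based brain masking has two intensity classes.

What the phantom does **not** emulate: head motion, eddy-current and EPI
distortion, partial-volume mixtures with gray matter, crossing fibers, and
atrophy-driven geometry change. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness to
those real-data confounds.

## Numerical choices

* **Tensor fit**: ordinary least squares on the log signal, matching the
  behavior of the era's tooling; the estimator is exact on noiseless
  monoexponential data (round-trip error ~10⁻¹² relative). A nonlinear LS
  fit exists only as an independent oracle in the tests. Non-positive
  signals are clamped to 10⁻⁶ of the signal maximum before the log.
  Negative eigenvalues are floored at 10⁻¹² for FA but kept raw otherwise.
* **Brain mask**: mean-b0 Otsu threshold, with a positive-signal fallback
  for degenerate (single-class) histograms. The emulated study is silent on
  masking.
* **FACT defaults**: FA stop 0.15, angle stop 35°, one seed per voxel
  (voxel centre), fixed step of half the smallest voxel dimension,
  trilinear direction interpolation with per-corner sign alignment; an
  exact 90° flip terminates the track. The study's Diffusion Toolkit
  parameters are unreported; these are declared assumptions, exposed in the
  configuration, not reproductions.
* **Coordinates**: TrackVis voxel-mm (0-based voxel indices × voxel size);
  .trk files round-trip at float32 precision and open in standard viewers.
* **Tract membership**: any-point membership in both seed and target masks
  (endpoint-only mode available); retained streamlines are trimmed to the
  last-seed-point → first-target-point sub-polyline and oriented
  seed→target. ROI masks are used exactly as labeled, no dilation.
* **Tract mean FA**: unweighted mean over the set of unique voxels visited
  by at least one streamline ("FA map region" reading); a per-point mean is
  available as an alternative. The 90% cohort criterion uses ceil
  (68.4 → 69 of 76).
* **Profiles**: "equidistant data points" is interpreted as
  arc-length-uniform per streamline (spacing L/99) — the only reading
  invariant to tracking step size. FA is sampled by trilinear interpolation
  (nearest available). Per-segment SE is across streamlines within subject
  for single-subject profiles and across subjects for cohort profiles.
  Single-ROI profiles anchor each streamline at its point nearest the
  ROI centroid and number segments toward the distal cut over the bundle's
  common extent; midline-split profiles cut at the x = grid-centre plane
  (a synthetic stand-in for the anatomical midsagittal plane).
* **Statistics**: per-subject annual % change uses the subject's own
  inter-scan interval (cohort mean 3.6 y as fallback); for three waves the
  per-subject rate is the mean of the two interval rates (the overall
  wave-1→3 rate is available as an option). Outlier exclusion is a single
  2.5-SD pass (SD with n−1), no re-iteration. Missing data: pairwise
  deletion for paired t-tests, listwise for RM-ANOVA (via
  `statsmodels.stats.anova.AnovaRM`; no sphericity correction). Degenerate
  zero-difference tests report p = 1 by convention. Bonferroni alphas are
  reported rounded to four decimals (0.05/22 → 0.0023, 0.05/100 → 0.0005),
  and significance in the package's own outputs always follows the
  computed corrected alpha. Summary statistics over printed change tables
  use the magnitude convention (all summarized rates share a sign, so
  signed and magnitude means agree).

## Validation experiments

`tractaging.experiments` defines the from-scratch measurements used by the
test suite and the acceptance script. Problem sizes: the noiseless
round-trip and geometry checks run on 30×16×12 to 48×80×16 grids; the
cohort-recovery experiment runs the full per-examination pipeline for
N = 76 subjects × 2 waves with one straight bundle in a compact 36×16×12
grid at 2 mm (a desk-scale stand-in for the cohort's field of view); the
null calibrations use 2000 replicates for the paired t and 500 for the
100-segment test. With these sizes the whole validation completes in a few
minutes on one CPU.

## Known limitations

* Single-tensor FACT cannot represent crossing or kissing fibers; tube
  phantoms do not probe that regime.
* Tract mean FA over visited voxels includes boundary voxels, which mildly
  attenuates estimated percentage change relative to the generative
  in-tube decline (the recovery experiment bounds this effect).
* The RM-ANOVA applies no sphericity correction, and no mixed-effects
  models are provided — the statistical layer reproduces a classical
  analysis, not the modern longitudinal-modeling alternative.
* Whether the emulated study required endpoint (vs any-point) ROI
  membership, and whether it pooled points or averaged within subject
  before group statistics, is unrecorded; the defaults here (any-point,
  within-subject averaging) are declared choices with config alternatives.
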