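# tractaging

Longitudinal diffusion-tensor tractometry, end to end: synthetic DWI cohort
simulation → tensor reconstruction and FA mapping → deterministic FACT
streamline tractography → seed/target tract-of-interest extraction →
100-segment along-tract FA profiling → cohort change statistics.

The package re-creates the analysis workflow of longitudinal aging studies
that track fractional anisotropy (FA) in subcortico-frontal white-matter
bundles over repeated MRI examinations ("waves"). Raw scans from such
cohorts are rarely shareable, so the package ships a first-class phantom
module: co-registered longitudinal DWI cohorts with known fiber geometry
and a known per-subject annual FA decline, giving every downstream stage an
analytic or generative ground truth. It is aimed at researchers who need a
tested, reproducible reference implementation of classical (tensor + FACT)
tractometry and its longitudinal statistics.

## The model in brief

* **Signal**: Stejskal–Tanner monoexponential, `S_k = S0 · exp(−b_k gᵏᵀ D gᵏ)`,
  with Rician noise built from two Gaussian channels of SD `S0/SNR`.
  The simulated protocol is 25 directions at b = 1000 s/mm² plus 5 b = 0
  volumes.
* **Tensor fit**: voxel-wise ordinary least squares on the log signal
  (7 unknowns: 6 tensor components + ln S0); FA is
  `sqrt(3/2)·‖λ − λ̄‖ / ‖λ‖` from the eigenvalues λ.
* **Tracking**: fiber assignment by continuous tracking (FACT) — from every
  voxel with FA ≥ 0.15, bidirectional propagation along the principal
  eigenvector with trilinear, sign-aligned direction interpolation;
  termination on leaving the volume, FA < 0.15, or a turn > 35° per step.
* **Tract extraction**: a streamline belongs to a seed→target connection if
  it touches both label regions; a bundle counts as detected with ≥ 20
  streamlines, and a connection enters group analysis when detected in at
  least 90% of subjects (ceil rule).
* **Tractometry**: each streamline is resampled to 100 arc-length-equidistant
  points (seed = segment 1); per-segment mean FA ± SE across streamlines,
  with single-ROI (corticospinal-style) and midline-split (callosal-style)
  variants.
* **Longitudinal statistics**: per-subject annual %ΔFA (own inter-scan
  interval), 2.5-SD outlier exclusion, paired t-tests (2 waves) or
  repeated-measures ANOVA (3 waves), Bonferroni-corrected alphas
  (0.05/22 = 0.0023 for tract means, 0.05/100 = 0.0005 for segments), and
  Pearson correlation of baseline age with yearly change.

## Worked example

```python
from tractaging.pipeline import RunConfig, run_pipeline
run_pipeline(RunConfig(outdir="demo", n_subjects=4, waves=2, rng_seed=11))
```

or, equivalently, `tractaging run-all --outdir demo --n-subjects 4 --waves 2
--rng-seed 11`. This simulates a 4-subject, 2-wave cohort with three phantom
bundles (straight, C-arc, S-curve; baseline FA 0.45, true decline
1.5 ± 0.5 %/yr, SNR 25), runs every stage, and writes report TSVs. The
resulting `demo/stats/change_table.tsv` contains:

```
connection  wave1_mean  wave2_mean  p_value   N  pct_change_per_year  M  significant
arc         0.402415    0.383986    ...       4  -1.236990            0  True
scurve      0.379680    0.366455    ...       4  -0.936673            0  True
straight    0.419580    0.395001    ...       4  -1.579490            0  False
```

`pct_change_per_year` is the cohort mean of per-subject annual % FA change —
all three estimates scatter around the generative −1.5 %/yr (a 4-subject
demo is noisy; at N = 76 the estimate lands within ±0.3 of truth, see the
acceptance suite). `N` is subjects used, `M` outliers excluded, and
`significant` flags p below the Bonferroni-corrected alpha. Re-running with
the same seed reproduces every report byte for byte.

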