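"""Validation experiments run under the emulated study's conditions.

These functions reproduce, from scratch, the quantities used to validate
the pipeline: exactness of the tensor fit in the noiseless limit, geometric
fidelity of FACT tracking, localization of along-tract effects, recovery of
a known cohort FA decline (N = 76, two waves 3.6 y apart, decline
1.5 +- 0.5 %/yr, SNR 25), and type-I calibration of the longitudinal tests.
They are used by both the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FAVolume, Geometry
from .dti import fit_fa, fit_tensor
from .phantom import (
    CurveBundleSpec,
    PhantomCohortSpec,
    default_scheme,
    eigenvalues_for_fa,
    rasterize_tensor_field,
    simulate_cohort,
    simulate_dwi,
)
from .stats import connection_change_table, paired_t, segmentwise_longitudinal_test
from .toi import Bundle, extract_bundle, tract_mean_fa
from .tracking import fact_track, streamline_length
from .tract_param import profile_single_roi

TRACE = 2.1e-3


# ---------------------------------------------------------------- round trip
def tensor_roundtrip_max_rel_error(fa: float = 0.45) -> float:
    """Max relative tensor error of fit_tensor(simulate_dwi(D)) noiseless."""
    grid = Geometry((30, 16, 12), (2.0, 2.0, 2.0))
    spec = CurveBundleSpec(
        np.array([[8.0, 16.0, 12.0], [52.0, 16.0, 12.0]]), 4.0, 20, 10, 1010
    )
    tensors, _ = rasterize_tensor_field(spec, grid, eigenvalues_for_fa(fa, TRACE))
    dwi = simulate_dwi(tensors, default_scheme(), s0=1000.0, snr=None)
    fitted = fit_tensor(dwi)
    scale = np.max(np.abs(tensors.components))
    return float(np.max(np.abs(fitted.components - tensors.components)) / scale)


# ------------------------------------------------------------ FACT geometry
def fact_straight_max_deviation_mm() -> float:
    """Max perpendicular deviation of a streamline in a uniform +x field."""
    shape = (20, 10, 8)
    geom = Geometry(shape, (2.0, 2.0, 2.0))
    evecs = np.zeros(shape + (3, 3))
    evecs[..., 0, 0] = evecs[..., 1, 1] = evecs[..., 2, 2] = 1.0
    fa = FAVolume(np.full(shape, 0.5), geom, np.ones(shape, bool))
    seed = np.zeros(shape, bool)
    seed[10, 5, 4] = True
    (pts,) = fact_track(evecs, fa, seed_mask=seed)
    return float(
        max(np.ptp(pts[:, 1]), np.ptp(pts[:, 2]))
    )


def fact_arc_length_error_pct() -> float:
    """Arc-length error (%) of the centerline-seeded streamline on a
    quarter-circle phantom, against the analytic arc length."""
    grid = Geometry((48, 80, 16), (1.0, 1.0, 1.0))
    theta = np.linspace(0.0, np.pi / 2, 400)
    center, radius = np.array([12.0, 64.0]), 24.0
    pts = np.stack(
        [center[0] + radius * np.sin(theta), center[1] - radius * np.cos(theta),
         8.0 + 0.0 * theta],
        axis=1,
    )
    spec = CurveBundleSpec(pts, 4.0, 20, 11, 1011, name="arc")
    tensors, _ = rasterize_tensor_field(spec, grid, eigenvalues_for_fa(0.45, TRACE))
    fa, _, evecs = fit_fa(simulate_dwi(tensors, default_scheme(), snr=None))
    streamlines, seeds = fact_track(evecs, fa, return_seeds=True)
    seed_mm = (seeds + 0.5) * np.asarray(grid.voxel_sizes)
    dist_to_axis = np.hypot(
        np.abs(np.linalg.norm(seed_mm[:, :2] - center, axis=1) - radius),
        np.abs(seed_mm[:, 2] - 8.0),
    )
    s = streamlines[int(np.argmin(dist_to_axis))]
    analytic = np.pi * radius / 2
    return float(abs(streamline_length(s) - analytic) / analytic * 100.0)


# ------------------------------------------------- tract mean FA brute force
def tract_mean_fa_brute_force_delta(seed: int = 0) -> float:
    """|tract_mean_fa - brute-force unique-voxel mean| on a random phantom."""
    rng = np.random.default_rng(seed)
    geom = Geometry((12, 12, 8), (2.0, 2.0, 2.0))
    fa_data = rng.uniform(0.1, 0.9, geom.shape)
    fa = FAVolume(fa_data, geom, np.ones(geom.shape, bool))
    streamlines = [
        np.cumsum(rng.uniform(0.3, 1.2, (25, 3)), axis=0) + [4.0, 4.0, 4.0]
        for _ in range(8)
    ]
    bundle = Bundle(1, 2, streamlines)
    got = tract_mean_fa(bundle, fa)
    seen = {
        tuple(v)
        for pts in streamlines
        for v in np.floor(pts / 2.0).astype(int)
        if all(0 <= v[d] < geom.shape[d] for d in range(3))
    }
    expected = float(np.mean([fa_data[v] for v in seen]))
    return abs(got - expected)


# --------------------------------------------------------- step localization
def step_localization_segment() -> int:
    """1-based segment at which a generative FA step placed 30% along the
    bundle appears in the single-ROI profile."""
    geom = Geometry((50, 10, 6), (2.0, 2.0, 2.0))
    data = np.full(geom.shape, 0.45)
    step_x_mm = 1.0 + 0.30 * 98.0
    data[int(step_x_mm / 2.0):, :, :] = 0.25
    fa = FAVolume(data, geom, np.ones(geom.shape, bool))
    roi = np.zeros(geom.shape, bool)
    roi[0, 4, 2] = True
    n = 50
    lines = [
        np.stack([np.linspace(1.0, 99.0, n), np.full(n, 9.0), np.full(n, 5.0)],
                 axis=1)
        for _ in range(4)
    ]
    prof = profile_single_roi(Bundle(1, 2, lines), fa, roi)
    mid = (0.45 + 0.25) / 2
    return int(np.argmax(prof.mean_fa < mid)) + 1


# --------------------------------------------------------- cohort experiment
def recovery_grid() -> Geometry:
    return Geometry((36, 16, 12), (2.0, 2.0, 2.0))


def recovery_bundle() -> CurveBundleSpec:
    return CurveBundleSpec(
        np.array([[10.0, 16.0, 12.0], [62.0, 16.0, 12.0]]), 4.0, 20, 10, 1010,
        name="straight",
    )


def run_cohort_pipeline(spec: PhantomCohortSpec,
                        bundle: CurveBundleSpec | None = None,
                        grid: Geometry | None = None) -> tuple[pd.DataFrame, float]:
    """Simulate a cohort and push every examination through the full
    imaging pipeline; returns (long cohort table, generative mean decline)."""
    if bundle is None:
        bundle = recovery_bundle()
    if grid is None:
        grid = recovery_grid()
    subject_waves, truths = simulate_cohort(spec, [bundle], grid)
    rows = []
    for sw in subject_waves:
        fa, _, evecs = fit_fa(sw.dwi)
        streamlines = fact_track(evecs, fa)
        extracted = extract_bundle(streamlines, sw.labels, bundle.seed_label,
                                   bundle.target_label, name=bundle.name)
        rows.append(
            {"subject": sw.subject, "wave": sw.wave, "connection": bundle.name,
             "fa": tract_mean_fa(extracted, fa), "age": sw.age,
             "interval_years": sw.interval_since_previous,
             "n_fibers": extracted.n_fibers}
        )
    true_mean = float(np.mean([t.true_decline_pct_per_year for t in truths]))
    return pd.DataFrame(rows), true_mean


def cohort_decline_recovery(seed: int, n_subjects: int = 76) -> dict:
    """Recover a 1.5 +- 0.5 %/yr cohort FA decline at SNR 25 (study design).

    Returns the pipeline's estimated cohort-mean annual % change, the
    generative truth, and the significance decision at the Bonferroni alpha
    for 22 tract comparisons (0.0023).
    """
    spec = PhantomCohortSpec(n_subjects=n_subjects, waves=2,
                             annual_decline_pct=(1.5, 0.5), snr=25.0,
                             rng_seed=seed)
    cohort, true_mean = run_cohort_pipeline(spec)
    result = connection_change_table(cohort, n_comparisons=22)[0]
    return {
        "estimated_pct_per_year": result.pct_change_per_year,
        "true_pct_per_year": -true_mean,
        "nominal_pct_per_year": -1.5,
        "p": result.p,
        "significant_at_0023": bool(result.significant),
        "n_used": result.n_used,
        "n_excluded": result.n_excluded,
    }


# ----------------------------------------------------------- null calibration
def null_paired_t_rejection_pct(seed: int, n_reps: int = 2000,
                                n_subjects: int = 76,
                                alpha: float = 0.05) -> float:
    """Type-I error (%) of the paired t-test under an i.i.d. Gaussian null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.normal(0.35, 0.03, n_subjects)
        b = a + rng.normal(0.0, 0.01, n_subjects)
        if paired_t(a, b).p < alpha:
            rejections += 1
    return 100.0 * rejections / n_reps


def null_segmentwise_significant_per_100(seed: int, n_reps: int = 500,
                                         n_subjects: int = 76,
                                         n_segments: int = 100) -> float:
    """Mean number of significant segments per 100 under the null at the
    segment-wise Bonferroni alpha (0.0005); expectation is 0.05."""
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_reps):
        base = rng.normal(0.35, 0.03, (n_subjects, 1, n_segments))
        noise = rng.normal(0.0, 0.01, (n_subjects, 2, n_segments))
        prof = np.repeat(base, 2, axis=1) + noise
        res = segmentwise_longitudinal_test(prof)
        total += int(res.significant.sum())
    return total / n_reps
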