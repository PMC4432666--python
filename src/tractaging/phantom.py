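"""Synthetic longitudinal DWI cohorts with known fiber geometry and FA truth.

The phantom emulates the acquisition of a longitudinal aging study: 25
diffusion directions at b = 1000 s/mm^2 plus 5 b = 0 volumes, 2-3 study
waves a mean of 3.6 years apart, and per-subject annual FA decline drawn
around a cohort mean.  Bundles are tubes around parametric centerlines; the
tensor inside a tube is axially symmetric with its principal eigenvector
along the local tangent, so every downstream stage (tensor fit, FACT
tracking, tract profiling, change statistics) has an analytic ground truth.

Decline is applied to the generative eigenvalues, not post hoc to FA maps,
so noisy FA estimates scatter around a known truth.  All waves of a subject
share one grid: the cohort is co-registered by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    DWISeries,
    Geometry,
    GradientScheme,
    InvalidParameterError,
    LabelVolume,
    OutOfBoundsError,
    TensorVolume,
)

# Typical adult white-matter trace; only anisotropy varies with "aging".
DEFAULT_TRACE = 2.1e-3  # mm^2/s
DEFAULT_SNR = 25.0
BACKGROUND_FA = 0.0


def default_scheme(n_directions: int = 25, n_b0: int = 5, b: float = 1000.0,
                   seed: int = 424242) -> GradientScheme:
    """Gradient table mimicking the study protocol (25 x b=1000 + 5 x b=0).

    Directions are a deterministic, reasonably uniform hemisphere sampling
    (golden-spiral points); the table itself was not published.
    """
    i = np.arange(n_directions)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = (i + 0.5) / n_directions  # upper hemisphere
    r = np.sqrt(1.0 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    dirs = np.concatenate([np.zeros((n_b0, 3)), dirs], axis=0)
    return GradientScheme(bvals, dirs)


def eigenvalues_for_fa(target_fa: float, trace: float = DEFAULT_TRACE) -> np.ndarray:
    """Axially symmetric eigenvalue triple (l1 >= l2 = l3) with given FA and trace.

    Closed-form inverse of the FA formula for prolate tensors:
        l2 = l3 = T/3 * (1 - f / sqrt(3 - 2 f^2)),   l1 = T - 2 l2.
    """
    if not (0.0 <= target_fa < 1.0):
        raise InvalidParameterError(f"target FA must be in [0, 1), got {target_fa}")
    if trace <= 0:
        raise InvalidParameterError("trace must be positive")
    f = float(target_fa)
    l23 = trace / 3.0 * (1.0 - f / np.sqrt(3.0 - 2.0 * f**2))
    l1 = trace - 2.0 * l23
    return np.array([l1, l23, l23])


@dataclass(frozen=True)
class CurveBundleSpec:
    """A tube phantom: centerline control points (mm), radius, ROI labels."""

    centerline: np.ndarray  # (n_ctrl, 3) mm, interpreted as a polyline
    radius: float  # mm
    n_streamlines: int
    seed_label: int
    target_label: int
    name: str = "bundle"

    def __post_init__(self) -> None:
        pts = np.asarray(self.centerline, dtype=float).reshape(-1, 3)
        if pts.shape[0] < 2:
            raise InvalidParameterError("centerline needs >=2 control points")
        if self.radius <= 0:
            raise InvalidParameterError("radius must be positive")
        if self.n_streamlines < 1:
            raise InvalidParameterError("n_streamlines must be >=1")
        object.__setattr__(self, "centerline", pts)

    def dense_polyline(self, spacing: float = 0.05) -> np.ndarray:
        """Densely resampled centerline (arc-length-uniform, ~`spacing` mm)."""
        pts = self.centerline
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        n = max(int(np.ceil(total / spacing)) + 1, 2)
        si = np.linspace(0.0, total, n)
        out = np.empty((n, 3))
        for d in range(3):
            out[:, d] = np.interp(si, s, pts[:, d])
        return out


@dataclass(frozen=True)
class PhantomCohortSpec:
    """Design of a synthetic longitudinal cohort.

    Defaults mirror the emulated study: waves a mean of 3.6 years apart with
    +-0.4 y per-subject jitter, baseline age 59 +- 7 y, and per-subject true
    annual FA decline drawn from N(mean, sd) of `annual_decline_pct`.
    """

    n_subjects: int
    waves: int = 2
    interval_years: tuple[float, float] = (3.6, 0.4)  # (mean, jitter SD)
    baseline_fa: float = 0.45
    annual_decline_pct: tuple[float, float] = (1.5, 0.5)  # (mean, SD), % per year
    baseline_age: tuple[float, float] = (59.0, 7.0)
    snr: float = DEFAULT_SNR
    s0: float = 1000.0
    trace: float = DEFAULT_TRACE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_fa < 1.0):
            raise InvalidParameterError("baseline_fa must be in (0, 1)")
        if self.n_subjects < 2:
            raise InvalidParameterError("need at least 2 subjects")
        if self.snr <= 0:
            raise InvalidParameterError("snr must be positive")
        if self.waves not in (2, 3):
            raise InvalidParameterError("waves must be 2 or 3")


def _tangents(polyline: np.ndarray) -> np.ndarray:
    """Unit tangents by central differences (one-sided at the ends)."""
    t = np.gradient(polyline, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _axially_symmetric_tensor(tangent: np.ndarray, evals: np.ndarray) -> np.ndarray:
    """D = l2*I + (l1-l2) t t^T for axially symmetric triples (vectorised)."""
    l1, l2, l3 = evals
    if not np.isclose(l2, l3):
        raise InvalidParameterError("rasterizer expects axially symmetric eigenvalues")
    outer = tangent[..., :, None] * tangent[..., None, :]
    return l2 * np.eye(3) + (l1 - l2) * outer


def rasterize_tensor_field(
    spec: CurveBundleSpec,
    grid: Geometry,
    evals: np.ndarray,
    background_evals: np.ndarray | None = None,
    label_volume: LabelVolume | None = None,
    label_radius: float | None = None,
) -> tuple[TensorVolume, LabelVolume]:
    """Paint a tube of oriented tensors (and its end labels) into a grid.

    Voxels whose centre lies within `spec.radius` of the centerline get an
    axially symmetric tensor with principal eigenvector along the local
    tangent; background voxels get isotropic tensors of the same trace.
    Seed/target labels are painted as spheres around the two curve ends.
    Pass an existing `label_volume` to accumulate several bundles.
    """
    evals = np.asarray(evals, dtype=float)
    poly = spec.dense_polyline()
    if not bool(np.all(grid.contains_mm(poly))):
        raise OutOfBoundsError("bundle centerline exits the grid")
    tangents = _tangents(poly)

    centers = grid.voxel_centers_mm().reshape(-1, 3)
    tree = cKDTree(poly)
    dist, nearest = tree.query(centers, workers=-1)
    inside = dist <= spec.radius
    # finite tube, not a capsule: drop voxels beyond the end planes so the
    # bundle's FA support ends where the centerline ends
    for end_idx, outward_sign in ((0, -1.0), (poly.shape[0] - 1, 1.0)):
        at_end = inside & (nearest == end_idx)
        if at_end.any():
            outward = outward_sign * tangents[end_idx]
            axial = (centers[at_end] - poly[end_idx]) @ outward
            drop = np.where(at_end)[0][axial > 1e-9]
            inside[drop] = False

    if background_evals is None:
        trace = float(evals.sum())
        background_evals = np.full(3, trace / 3.0)
    bg = np.asarray(background_evals, dtype=float)

    mats = np.empty((centers.shape[0], 3, 3))
    mats[:] = np.diag(bg)
    if inside.any():
        t_in = tangents[nearest[inside]]
        mats[inside] = _axially_symmetric_tensor(t_in, evals)
    tensors = TensorVolume.from_matrices(mats.reshape(grid.shape + (3, 3)), grid)

    if label_volume is None:
        labels = np.zeros(grid.shape, dtype=np.int32)
    else:
        labels = label_volume.data.copy()
    r_lab = spec.radius * 1.5 if label_radius is None else label_radius
    for endpoint, lab in ((poly[0], spec.seed_label), (poly[-1], spec.target_label)):
        d_end = np.linalg.norm(centers - endpoint, axis=1)
        labels.reshape(-1)[d_end <= r_lab] = lab
    return tensors, LabelVolume(labels, grid)


def simulate_dwi(
    tensors: TensorVolume,
    scheme: GradientScheme,
    s0: float | np.ndarray = 1000.0,
    snr: float | None = DEFAULT_SNR,
    rng_seed: int = 0,
) -> DWISeries:
    """Stejskal-Tanner signal S = S0 exp(-b g^T D g) with Rician noise.

    Rician noise is built from two independent Gaussian channels of
    SD = mean(S0)/snr (the b0 SNR definition); `snr=None` is noiseless.
    `s0` may be a scalar or a per-voxel map (e.g. to carve an air border).
    """
    s0_arr = np.asarray(s0, dtype=float)
    if np.any(s0_arr <= 0):
        raise InvalidParameterError("s0 must be positive")
    mats = tensors.as_matrices()
    g = scheme.directions
    b = scheme.bvalues
    # quadratic form g^T D g for every voxel and direction
    quad = np.einsum("kd,...de,ke->...k", g, mats, g)
    signal = np.exp(-b * quad)
    signal = signal * (s0_arr[..., None] if s0_arr.ndim else s0_arr)
    if snr is not None:
        if snr <= 0:
            raise InvalidParameterError("snr must be positive")
        sigma = float(np.mean(s0_arr)) / snr if s0_arr.ndim else float(s0_arr) / snr
        rng = np.random.default_rng(rng_seed)
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)
    return DWISeries(signal, tensors.geometry, scheme)


def default_grid() -> Geometry:
    """Desk-scale phantom grid: 40 x 40 x 20 voxels at 2 mm isotropic."""
    return Geometry((40, 40, 20), (2.0, 2.0, 2.0))


def default_bundles() -> list[CurveBundleSpec]:
    """Three fixture bundles: straight, C-shaped arc, S-curve.

    Covers constant, curved and inflected tangent fields, the geometries that
    stress a deterministic FACT tracker.  Labels follow FreeSurfer-style
    conventions loosely (two-digit seed IDs, four-digit cortical targets).
    """
    straight = CurveBundleSpec(
        centerline=np.array([[10.0, 20.0, 20.0], [70.0, 20.0, 20.0]]),
        radius=4.0, n_streamlines=30, seed_label=10, target_label=1010,
        name="straight",
    )
    # C-shaped half-arc in the x-y plane, radius 24 mm, at z = 30 mm
    theta = np.linspace(-np.pi / 2, np.pi / 2, 61)
    arc_pts = np.stack(
        [40.0 + 24.0 * np.cos(theta), 44.0 + 24.0 * np.sin(theta), 30.0 + 0.0 * theta],
        axis=1,
    )
    arc = CurveBundleSpec(
        centerline=arc_pts, radius=4.0, n_streamlines=30,
        seed_label=11, target_label=1011, name="arc",
    )
    s = np.linspace(0.0, 1.0, 81)
    s_pts = np.stack(
        [12.0 + 56.0 * s, 58.0 + 8.0 * np.sin(2.0 * np.pi * s), 12.0 + 0.0 * s],
        axis=1,
    )
    scurve = CurveBundleSpec(
        centerline=s_pts, radius=4.0, n_streamlines=30,
        seed_label=12, target_label=1012, name="scurve",
    )
    return [straight, arc, scurve]


@dataclass
class SubjectWave:
    """One simulated examination of one subject."""

    subject: str
    wave: int
    age: float
    interval_since_previous: float  # years; 0 for wave 1
    dwi: DWISeries
    labels: LabelVolume
    true_fa: dict[str, float]  # bundle name -> generative FA at this wave


@dataclass
class CohortTruth:
    """Ground truth record for one subject/bundle: the generative decline."""

    subject: str
    bundle: str
    baseline_fa: float
    true_decline_pct_per_year: float


def simulate_cohort(
    spec: PhantomCohortSpec,
    bundles: list[CurveBundleSpec] | None = None,
    grid: Geometry | None = None,
) -> tuple[list[SubjectWave], list[CohortTruth]]:
    """Simulate a co-registered longitudinal cohort with known FA decline.

    Every subject gets the same bundle geometry; the generative FA of each
    bundle at wave w is baseline * (1 - rate/100)**(elapsed years), with the
    per-subject rate drawn once from the cohort decline distribution.  Rician
    noise is freshly drawn per subject and wave; identical `rng_seed` gives a
    bit-identical cohort.
    """
    if bundles is None:
        bundles = default_bundles()
    if grid is None:
        grid = default_grid()
    rng = np.random.default_rng(spec.rng_seed)

    n = spec.n_subjects
    rates = rng.normal(spec.annual_decline_pct[0], spec.annual_decline_pct[1], n)
    ages0 = rng.normal(spec.baseline_age[0], spec.baseline_age[1], n)
    mean_iv, jitter = spec.interval_years
    intervals = np.clip(
        rng.normal(mean_iv, jitter, (n, spec.waves - 1)), 0.5, None
    )
    noise_seeds = rng.integers(0, 2**31 - 1, size=(n, spec.waves))

    # s0 map with a 2-voxel air border so Otsu masking has two classes.
    s0_map = np.full(grid.shape, spec.s0 * 0.02)
    s0_map[2:-2, 2:-2, 2:-2] = spec.s0

    truths = [
        CohortTruth(f"sub-{i:03d}", b.name, spec.baseline_fa, float(rates[i]))
        for i in range(n) for b in bundles
    ]

    subject_waves: list[SubjectWave] = []
    for i in range(n):
        elapsed = 0.0
        for w in range(spec.waves):
            interval = 0.0 if w == 0 else float(intervals[i, w - 1])
            elapsed += interval
            fa_w = spec.baseline_fa * (1.0 - rates[i] / 100.0) ** elapsed
            fa_w = float(np.clip(fa_w, 0.0, 0.99))
            tensors, labels = None, None
            for b in bundles:
                tensors_b, labels = rasterize_tensor_field(
                    b, grid, eigenvalues_for_fa(fa_w, spec.trace),
                    label_volume=labels,
                )
                if tensors is None:
                    tensors = tensors_b
                else:
                    # overlay: replace background voxels of the running field
                    bundle_mask = ~np.isclose(
                        tensors_b.components[..., 0], spec.trace / 3.0
                    )
                    tensors.components[bundle_mask] = tensors_b.components[bundle_mask]
            dwi = simulate_dwi(
                tensors, default_scheme(), s0=s0_map, snr=spec.snr,
                rng_seed=int(noise_seeds[i, w]),
            )
            subject_waves.append(
                SubjectWave(
                    subject=f"sub-{i:03d}", wave=w + 1,
                    age=float(ages0[i] + elapsed),
                    interval_since_previous=interval,
                    dwi=dwi, labels=labels,
                    true_fa={b.name: fa_w for b in bundles},
                )
            )
    return subject_waves, truths


def write_cohort(subject_waves, truths, outdir) -> None:
    """Write per-subject per-wave NIfTI + bval/bvec and a ground-truth TSV."""
    import os

    os.makedirs(outdir, exist_ok=True)
    truth_rows = ["subject\twave\tbundle\ttrue_fa\ttrue_decline_pct_per_year\tage\tinterval_years"]
    decline = {(t.subject, t.bundle): t.true_decline_pct_per_year for t in truths}
    for sw in subject_waves:
        stem = os.path.join(outdir, f"{sw.subject}_wave-{sw.wave}")
        sw.dwi.to_nifti(stem + "_dwi.nii.gz")
        sw.labels.to_nifti(stem + "_labels.nii.gz")
        sw.dwi.scheme.to_files(stem + ".bval", stem + ".bvec")
        for bundle, fa in sorted(sw.true_fa.items()):
            truth_rows.append(
                f"{sw.subject}\t{sw.wave}\t{bundle}\t{fa:.6f}"
                f"\t{decline[(sw.subject, bundle)]:.6f}\t{sw.age:.2f}"
                f"\t{sw.interval_since_previous:.3f}"
            )
    with open(os.path.join(outdir, "ground_truth.tsv"), "w") as fh:
        fh.write("\n".join(truth_rows) + "\n")
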