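"""Tract-of-interest extraction and cohort detection criteria.

Whole-volume streamlines are filtered to those connecting a seed and a
target label region (any-point membership by default, as used for
subcortico-frontal connections), trimmed to the seed->target sub-polyline.
Bundle-level and cohort-level thresholds follow the emulated study: a
bundle counts as detected when it has at least 20 streamlines, and a
connection enters group analysis only when detected in at least 90% of the
cohort (ceil rule, so 68.4 -> 69 subjects of 76).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FAVolume, Geometry, GeometryError, LabelVolume

MIN_FIBERS_DEFAULT = 20
COHORT_FRACTION_DEFAULT = 0.9


@dataclass
class Bundle:
    """A named set of streamlines connecting one seed and one target label."""

    seed_label: int
    target_label: int
    streamlines: list = field(default_factory=list)
    name: str = ""

    @property
    def n_fibers(self) -> int:
        return len(self.streamlines)


def _points_in_mask(points: np.ndarray, mask: np.ndarray, geom: Geometry) -> np.ndarray:
    """Boolean per-point membership: the containing voxel is in the mask."""
    vox = np.floor(np.asarray(points) / np.asarray(geom.voxel_sizes)).astype(int)
    shape = np.asarray(mask.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    out = np.zeros(points.shape[0], dtype=bool)
    if inside.any():
        v = vox[inside]
        out[inside] = mask[v[:, 0], v[:, 1], v[:, 2]]
    return out


def _trim(points: np.ndarray, in_seed: np.ndarray, in_target: np.ndarray) -> np.ndarray:
    """Maximal sub-polyline from the last seed point to the first target point.

    If the streamline runs target->seed, the trimmed piece is reversed so the
    result is always oriented seed->target.
    """
    seed_idx = np.where(in_seed)[0]
    tar_idx = np.where(in_target)[0]
    # forward orientation: a seed point precedes a target point
    cand_fwd = seed_idx[seed_idx < tar_idx.max() + 1]
    if cand_fwd.size:
        a = int(cand_fwd.max())
        after = tar_idx[tar_idx >= a]
        if after.size:
            b = int(after.min())
            if b > a:
                return points[a : b + 1]
    # reversed orientation: a target point precedes a seed point
    cand_rev = tar_idx[tar_idx < seed_idx.max() + 1]
    if cand_rev.size:
        b = int(cand_rev.min())
        before = seed_idx[seed_idx >= b]
        if before.size:
            a = int(before.max())
            if a > b:
                return points[b : a + 1][::-1]
    # degenerate interleaving: keep the widest seed->target span
    a, b = int(seed_idx.min()), int(tar_idx.max())
    lo, hi = min(a, b), max(a, b)
    seg = points[lo : hi + 1]
    return seg if a <= b else seg[::-1]


def extract_bundle(
    streamlines: list,
    labels: LabelVolume,
    seed_label: int,
    target_label: int,
    geometry: Geometry | None = None,
    endpoint_only: bool = False,
    name: str = "",
) -> Bundle:
    """Select streamlines touching both the seed and the target region.

    A streamline is retained iff it has at least one point in each mask
    (`endpoint_only=True` restricts membership to the two endpoints), and is
    trimmed to the sub-polyline between its last seed-mask point and first
    target-mask point, oriented seed->target.
    """
    geom = geometry if geometry is not None else labels.geometry
    if tuple(geom.shape) != tuple(labels.geometry.shape):
        raise GeometryError("label volume does not match tracking space")
    seed_mask = labels.mask_for(seed_label)
    target_mask = labels.mask_for(target_label)
    bundle = Bundle(seed_label, target_label, [], name=name)
    if not seed_mask.any() or not target_mask.any():
        warnings.warn(
            f"label {seed_label if not seed_mask.any() else target_label} "
            "absent from volume; returning empty bundle",
            stacklevel=2,
        )
        return bundle
    for pts in streamlines:
        pts = np.asarray(pts, dtype=float)
        in_seed = _points_in_mask(pts, seed_mask, geom)
        in_tar = _points_in_mask(pts, target_mask, geom)
        if endpoint_only:
            keep = np.zeros_like(in_seed)
            keep[[0, -1]] = True
            in_seed = in_seed & keep
            in_tar = in_tar & keep
        if seed_label == target_label:
            # degenerate query: require two disjoint visits to the mask
            runs = np.flatnonzero(np.diff(in_seed.astype(int)) != 0)
            n_runs = (runs.size + (1 if in_seed[0] else 0) + (1 if in_seed[-1] else 0)) // 2
            if not (in_seed.any() and n_runs >= 2):
                continue
        elif not (in_seed.any() and in_tar.any()):
            continue
        trimmed = _trim(pts, in_seed, in_tar)
        if trimmed.shape[0] >= 2:
            bundle.streamlines.append(trimmed)
    return bundle


def bundle_passes_threshold(bundle: Bundle, min_fibers: int = MIN_FIBERS_DEFAULT) -> bool:
    """Detection rule: at least `min_fibers` continuous fibers (inclusive)."""
    return bundle.n_fibers >= min_fibers


@dataclass
class DetectionMatrix:
    """Per-connection count of subjects in whom the bundle was detected."""

    counts: pd.DataFrame  # index: seed names, columns: target names; NaN = never
    cohort_size: int

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy(dtype=float)
        good = np.isnan(vals) | ((vals >= 0) & (vals <= self.cohort_size))
        if not good.all():
            raise ValueError("detection counts outside [0, cohort size]")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", na_rep="NA")


def cohort_detection_filter(
    matrix: DetectionMatrix, fraction: float = COHORT_FRACTION_DEFAULT
) -> list[tuple[str, str]]:
    """Connections detected in at least ceil(fraction * cohort) subjects."""
    if matrix.cohort_size < 1:
        raise ValueError("cohort size must be >= 1")
    need = math.ceil(fraction * matrix.cohort_size)
    out = []
    for seed in matrix.counts.index:
        for target in matrix.counts.columns:
            v = matrix.counts.loc[seed, target]
            if pd.notna(v) and v >= need:
                out.append((seed, target))
    return out


def visited_voxels(bundle: Bundle, geom: Geometry) -> np.ndarray:
    """Unique voxel indices visited by any member streamline, shape (n, 3)."""
    all_vox = []
    for pts in bundle.streamlines:
        vox = np.floor(np.asarray(pts) / np.asarray(geom.voxel_sizes)).astype(int)
        all_vox.append(vox)
    if not all_vox:
        return np.empty((0, 3), dtype=int)
    vox = np.concatenate(all_vox, axis=0)
    shape = np.asarray(geom.shape)
    vox = vox[np.all((vox >= 0) & (vox < shape), axis=1)]
    return np.unique(vox, axis=0)


def tract_mean_fa(bundle: Bundle, fa: FAVolume, per_point: bool = False) -> float:
    """Grand-average FA of the map region intersected by the tract.

    Default: unweighted mean over the set of unique voxels visited by at
    least one member streamline (each voxel counted once).  With
    `per_point=True`, the mean is instead taken over all streamline sample
    points (trilinear interpolation), which weights by point density.
    """
    if bundle.n_fibers == 0:
        return float("nan")
    if per_point:
        from scipy.ndimage import map_coordinates

        vals = []
        filled = fa.filled(np.nan)
        for pts in bundle.streamlines:
            vox = fa.geometry.mm_to_voxel(np.asarray(pts))
            vals.append(map_coordinates(filled, vox.T, order=1, mode="nearest"))
        return float(np.nanmean(np.concatenate(vals)))
    vox = visited_voxels(bundle, fa.geometry)
    if vox.size == 0:
        return float("nan")
    vals = fa.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    ok = fa.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    if not ok.any():
        return float("nan")
    return float(np.mean(vals[ok]))
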