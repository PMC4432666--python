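"""Deterministic FACT streamline tractography.

Fiber assignment by continuous tracking: from every voxel whose FA exceeds
the termination threshold, a streamline is propagated bidirectionally along
the principal eigenvector of the diffusion tensor, stepping a fixed fraction
of the voxel size with trilinearly interpolated, sign-aligned directions.
Propagation stops when the streamline leaves the volume, enters a voxel with
FA below threshold, or turns more sharply than the angular limit.

Coordinates are TrackVis "voxel-mm": 0-based voxel indices scaled by voxel
size.  Written .trk files open directly in standard viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.trk import TrkFile
from scipy.ndimage import map_coordinates

from .core import FAVolume, Geometry, GeometryError, InvalidParameterError


@dataclass(frozen=True)
class TrackingParams:
    """FACT parameters (the emulated study did not publish its values)."""

    fa_stop: float = 0.15
    angle_stop: float = 35.0  # degrees per step
    step_fraction: float = 0.5  # of the smallest voxel dimension
    seeds_per_voxel: int = 1
    max_steps: int = 2000

    def __post_init__(self) -> None:
        if not (0.0 <= self.fa_stop < 1.0):
            raise InvalidParameterError("fa_stop must be in [0, 1)")
        if not (0.0 < self.angle_stop <= 90.0):
            raise InvalidParameterError("angle_stop must be in (0, 90] degrees")


def streamline_length(points: np.ndarray) -> float:
    """Arc length of a polyline in mm."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidParameterError("streamline needs >=2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _interp_fa(fa_filled: np.ndarray, geom: Geometry, pts_mm: np.ndarray) -> np.ndarray:
    vox = geom.mm_to_voxel(pts_mm)
    return map_coordinates(fa_filled, vox.T, order=1, mode="constant", cval=0.0)


def _interp_direction(
    e1: np.ndarray, geom: Geometry, pts_mm: np.ndarray, ref: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of a line field with per-corner sign alignment.

    Principal eigenvectors are axes (sign-ambiguous); each of the 8 corner
    vectors is flipped to a non-negative dot product with the reference
    direction before blending, then the blend is renormalised.
    """
    vox = geom.mm_to_voxel(pts_mm)
    nx, ny, nz = e1.shape[:3]
    base = np.floor(vox).astype(int)
    frac = vox - base
    out = np.zeros_like(ref)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ix = np.clip(base[:, 0] + dx, 0, nx - 1)
                iy = np.clip(base[:, 1] + dy, 0, ny - 1)
                iz = np.clip(base[:, 2] + dz, 0, nz - 1)
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                v = e1[ix, iy, iz]
                sign = np.where(np.einsum("ij,ij->i", v, ref) < 0, -1.0, 1.0)
                out += w[:, None] * sign[:, None] * v
    norms = np.linalg.norm(out, axis=1)
    ok = norms > 1e-12
    out[ok] /= norms[ok, None]
    return out, ok


def _propagate(
    starts: np.ndarray,
    init_dirs: np.ndarray,
    e1: np.ndarray,
    fa_filled: np.ndarray,
    geom: Geometry,
    params: TrackingParams,
    step: float,
) -> list[np.ndarray]:
    """March all seeds simultaneously; return the list of half-tracks."""
    n = starts.shape[0]
    cos_limit = np.cos(np.deg2rad(params.angle_stop))
    pos = starts.copy()
    dirs = init_dirs.copy()
    tracks: list[list[np.ndarray]] = [[starts[i]] for i in range(n)]
    active = np.ones(n, dtype=bool)
    for _ in range(params.max_steps):
        if not active.any():
            break
        idx = np.where(active)[0]
        nxt = pos[idx] + step * dirs[idx]
        inside = geom.contains_mm(nxt)
        fa_ok = np.zeros(len(idx), dtype=bool)
        fa_ok[inside] = _interp_fa(fa_filled, geom, nxt[inside]) >= params.fa_stop
        ok = inside & fa_ok
        new_dirs = np.zeros_like(dirs[idx])
        if ok.any():
            nd, nonzero = _interp_direction(e1, geom, nxt[ok], dirs[idx][ok])
            cosang = np.einsum("ij,ij->i", nd, dirs[idx][ok])
            # tie-break at an exact 90-degree flip: terminate
            turn_ok = nonzero & (cosang >= cos_limit) & (cosang > 0.0)
            tmp = np.zeros_like(ok)
            tmp[np.where(ok)[0][turn_ok]] = True
            new_dirs[ok] = nd
            ok = tmp
        for j, gi in enumerate(idx):
            if ok[j]:
                tracks[gi].append(nxt[j])
        pos[idx[ok]] = nxt[ok]
        dirs[idx[ok]] = new_dirs[ok]
        active[idx[~ok]] = False
    return [np.asarray(t) for t in tracks]


def fact_track(
    evecs: np.ndarray,
    fa: FAVolume,
    params: TrackingParams | None = None,
    seed_mask: np.ndarray | None = None,
    return_seeds: bool = False,
) -> list[np.ndarray] | tuple[list[np.ndarray], np.ndarray]:
    """Whole-volume deterministic FACT tractography.

    `evecs` is the (X, Y, Z, 3, 3) eigenvector array from
    `dti.tensor_eigensystem`; the principal eigenvector is column 0.
    Returns streamlines as (n_points, 3) float arrays in voxel-mm
    coordinates, ordered by seed voxel (deterministic).  With
    `return_seeds=True` also returns the (n, 3) array of seed voxel indices
    (streamline provenance).
    """
    if params is None:
        params = TrackingParams()
    if evecs.shape[:3] != tuple(fa.geometry.shape):
        raise GeometryError("eigenvector field and FA map geometry mismatch")
    geom = fa.geometry
    e1 = np.ascontiguousarray(evecs[..., :, 0])
    fa_filled = fa.filled(0.0)

    seeds_ok = fa.mask & (fa.filled(0.0) >= params.fa_stop)
    if seed_mask is not None:
        seeds_ok = seeds_ok & seed_mask
    seed_idx = np.argwhere(seeds_ok)
    if seed_idx.size == 0:
        return ([], np.empty((0, 3), dtype=int)) if return_seeds else []
    starts = (seed_idx + 0.5) * np.asarray(geom.voxel_sizes)
    init = e1[seed_idx[:, 0], seed_idx[:, 1], seed_idx[:, 2]]
    norms = np.linalg.norm(init, axis=1)
    good = norms > 1e-12
    starts, init = starts[good], init[good] / norms[good, None]
    seed_idx = seed_idx[good]

    step = params.step_fraction * float(min(geom.voxel_sizes))
    fwd = _propagate(starts, init, e1, fa_filled, geom, params, step)
    bwd = _propagate(starts, -init, e1, fa_filled, geom, params, step)

    streamlines, kept = [], []
    for i, (f, b) in enumerate(zip(fwd, bwd)):
        pts = np.concatenate([b[::-1], f[1:]], axis=0)
        if pts.shape[0] >= 2:
            streamlines.append(pts)
            kept.append(i)
    if return_seeds:
        return streamlines, seed_idx[kept]
    return streamlines


def save_trk(path, streamlines: list[np.ndarray], geometry: Geometry) -> None:
    """Write streamlines as a TrackVis .trk file (voxel-mm convention)."""
    affine_to_rasmm = np.asarray(geometry.affine, dtype=float).copy()
    # voxel-mm -> voxel -> rasmm
    scale = np.diag([1.0 / geometry.voxel_sizes[0], 1.0 / geometry.voxel_sizes[1],
                     1.0 / geometry.voxel_sizes[2], 1.0])
    tg = Tractogram(streamlines, affine_to_rasmm=affine_to_rasmm @ scale)
    header = {
        "dimensions": np.asarray(geometry.shape, dtype=np.int16),
        "voxel_sizes": np.asarray(geometry.voxel_sizes, dtype=np.float32),
        "voxel_to_rasmm": np.asarray(geometry.affine, dtype=np.float32),
        "voxel_order": "RAS",
    }
    TrkFile(tg, header=header).save(str(path))


def load_trk(path, geometry: Geometry) -> list[np.ndarray]:
    """Read a .trk file back into voxel-mm streamlines."""
    trk = TrkFile.load(str(path))
    tg = trk.tractogram
    rasmm_to_voxelmm = np.diag(list(geometry.voxel_sizes) + [1.0]) @ np.linalg.inv(
        np.asarray(geometry.affine, dtype=float)
    )
    out = []
    for s in tg.streamlines:
        pts = np.asarray(s, dtype=np.float64)
        pts = pts @ rasmm_to_voxelmm[:3, :3].T + rasmm_to_voxelmm[:3, 3]
        out.append(pts)
    return out
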