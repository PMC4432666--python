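"""Diffusion tensor reconstruction and fractional anisotropy.

The tensor is fitted voxel-wise by ordinary least squares on the
log-linearised Stejskal-Tanner signal model

    ln S_k = ln S0 - b_k * g_k^T D g_k,

seven unknowns per voxel (six unique tensor components and ln S0).  FA is
the standard normalised eigenvalue dispersion

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .core import (
    DWISeries,
    FAVolume,
    GradientScheme,
    InsufficientDataError,
    TensorVolume,
)

# Relative clamp applied to non-positive signals before taking logs.
SIGNAL_CLAMP_REL = 1e-6
# Floor for negative eigenvalues when computing FA (raw values are retained).
EIGENVALUE_FLOOR = 1e-12


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Log-linear design matrix, one row per volume.

    Columns: -b*gx^2, -b*gy^2, -b*gz^2, -2b*gx*gy, -2b*gx*gz, -2b*gy*gz, 1;
    the solution vector is (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0).
    """
    b = scheme.bvalues
    g = scheme.directions
    cols = [
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones_like(b),
    ]
    return np.stack(cols, axis=1)


def fit_tensor(dwi: DWISeries) -> TensorVolume:
    """Voxel-wise OLS tensor fit; exact on noiseless monoexponential data."""
    scheme = dwi.scheme
    n_b0 = int(np.sum(scheme.b0_mask))
    dw_dirs = scheme.directions[~scheme.b0_mask]
    n_distinct = len({tuple(np.round(d, 9)) for d in np.abs(dw_dirs)})
    if n_b0 < 1 or n_distinct < 6 or len(scheme) < 7:
        raise InsufficientDataError(
            "tensor fit needs >=1 b0 volume and >=6 distinct diffusion directions"
        )
    X = design_matrix(scheme)
    signals = dwi.data.reshape(-1, len(scheme))
    s0_scale = max(float(np.max(signals)), 1.0)
    clamped = np.maximum(signals, SIGNAL_CLAMP_REL * s0_scale)
    coefs, *_ = np.linalg.lstsq(X, np.log(clamped).T, rcond=None)
    comps = coefs[:6].T.reshape(dwi.geometry.shape + (6,))
    return TensorVolume(comps, dwi.geometry)


def tensor_eigensystem(tensors: TensorVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition of every voxel tensor.

    Returns (eigenvalues, eigenvectors, valid): eigenvalues sorted descending
    with shape (*grid, 3); eigenvectors with shape (*grid, 3, 3) where
    ``eigenvectors[..., :, i]`` is the unit eigenvector of ``eigenvalues[..., i]``;
    valid is False where a tensor is non-finite (those voxels get zeros).
    """
    mats = tensors.as_matrices()
    valid = np.all(np.isfinite(mats), axis=(-2, -1))
    safe = np.where(valid[..., None, None], mats, np.eye(3))
    evals, evecs = np.linalg.eigh(safe)
    # eigh returns ascending order
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    evals = np.where(valid[..., None], evals, 0.0)
    return evals, evecs, valid


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA of an eigenvalue triple (vectorised; all-zero triples give NaN)."""
    lam = np.asarray(evals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, np.nan)
    return np.clip(fa, 0.0, 1.0) if np.ndim(fa) else float(np.clip(fa, 0.0, 1.0))


def brain_mask(dwi: DWISeries) -> np.ndarray:
    """Foreground mask: mean b0 signal above its Otsu threshold.

    Falls back to "everything with positive signal" when the b0 histogram is
    effectively unimodal (pure phantom grids without an air background).
    """
    b0 = dwi.data[..., dwi.scheme.b0_mask].mean(axis=-1)
    lo, hi = float(b0.min()), float(b0.max())
    if hi <= 0 or (hi - lo) < 1e-9 * max(hi, 1.0):
        return b0 > 0
    thr = threshold_otsu(b0)
    mask = b0 > thr
    # Degenerate split (e.g. near-uniform histogram): keep positive voxels.
    if not mask.any():
        mask = b0 > 0
    return mask


def fa_volume(tensors: TensorVolume, mask: np.ndarray | None = None) -> FAVolume:
    """FA map from a tensor volume; negative eigenvalues floored first."""
    evals, _, valid = tensor_eigensystem(tensors)
    clamped = np.maximum(evals, EIGENVALUE_FLOOR)
    fa = fa_from_eigenvalues(clamped)
    if mask is None:
        mask = np.ones(tensors.geometry.shape, dtype=bool)
    mask = mask & valid & np.isfinite(fa)
    fa = np.where(mask, fa, np.nan)
    return FAVolume(fa, tensors.geometry, mask)


def fit_fa(dwi: DWISeries) -> tuple[FAVolume, np.ndarray, np.ndarray]:
    """Convenience: tensor fit -> (FA volume, eigenvalues, eigenvectors)."""
    tensors = fit_tensor(dwi)
    mask = brain_mask(dwi)
    evals, evecs, valid = tensor_eigensystem(tensors)
    fa = fa_volume(tensors, mask)
    return fa, evals, evecs
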