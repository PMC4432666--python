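"""Shared containers and errors for the tractometry pipeline.

Everything downstream works in one common space: a regular voxel grid with
anisotropic voxel sizes in mm.  Streamline coordinates follow the TrackVis
"voxel-mm" convention -- 0-based voxel indices scaled by the voxel size, so
the centre of voxel (i, j, k) sits at ((i+0.5)*dx, (j+0.5)*dy, (k+0.5)*dz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


class InvalidParameterError(ValueError):
    """A parameter violates its contract (e.g. FA outside [0, 1))."""


class InsufficientDataError(ValueError):
    """Not enough usable data to perform the requested fit or test."""


class GeometryError(ValueError):
    """Mismatched or inconsistent volume geometries."""


class OutOfBoundsError(ValueError):
    """A geometric object does not fit inside the target grid."""


@dataclass(frozen=True)
class Geometry:
    """Voxel grid geometry: shape, voxel sizes (mm) and voxel->world affine."""

    shape: tuple[int, int, int]
    voxel_sizes: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise InvalidParameterError(f"bad grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_sizes):
            raise InvalidParameterError("voxel sizes must be positive")
        if self.affine is None:
            aff = np.diag(list(self.voxel_sizes) + [1.0])
            object.__setattr__(self, "affine", aff)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    def voxel_centers_mm(self) -> np.ndarray:
        """All voxel centres in voxel-mm coordinates, shape (*grid, 3)."""
        idx = np.indices(self.shape, dtype=float)
        centers = (np.stack(idx, axis=-1) + 0.5) * np.asarray(self.voxel_sizes)
        return centers

    def mm_to_voxel(self, pts_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates (voxel centres at integers)."""
        return np.asarray(pts_mm, dtype=float) / np.asarray(self.voxel_sizes) - 0.5

    def contains_mm(self, pts_mm: np.ndarray) -> np.ndarray:
        v = np.asarray(pts_mm) / np.asarray(self.voxel_sizes)
        upper = np.asarray(self.shape, dtype=float)
        return np.all((v >= 0.0) & (v <= upper), axis=-1)

    def matches(self, other: "Geometry") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_sizes, other.voxel_sizes)
            and np.allclose(self.affine, other.affine)
        )


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion gradient table: b-values (s/mm^2) and unit directions."""

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvalues, dtype=float).ravel()
        dirs = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != dirs.shape[0]:
            raise InvalidParameterError("bvalues and directions differ in length")
        if not np.any(bvals == 0):
            raise InvalidParameterError("scheme needs at least one b=0 entry")
        dw = bvals > 0
        norms = np.linalg.norm(dirs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise InvalidParameterError("b>0 directions must be unit vectors")
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "directions", dirs)

    def __len__(self) -> int:
        return self.bvalues.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    def to_files(self, bval_path, bvec_path) -> None:
        """Write FSL-dialect bval (one row) / bvec (three rows) files."""
        with open(bval_path, "w") as fh:
            fh.write(" ".join(f"{b:g}" for b in self.bvalues) + "\n")
        with open(bvec_path, "w") as fh:
            for axis in range(3):
                fh.write(" ".join(f"{v:.10g}" for v in self.directions[:, axis]) + "\n")

    @classmethod
    def from_files(cls, bval_path, bvec_path) -> "GradientScheme":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals, bvecs)


def _nifti_roundtrip(data: np.ndarray, geometry: Geometry) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(data), geometry.affine)
    img.header.set_zooms(tuple(geometry.voxel_sizes) + (1.0,) * (data.ndim - 3))
    return img


@dataclass
class DWISeries:
    """4D diffusion-weighted series plus its gradient scheme."""

    data: np.ndarray  # (X, Y, Z, n_volumes)
    geometry: Geometry
    scheme: GradientScheme

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise InvalidParameterError("DWI data must be 4D")
        if self.data.shape[-1] != len(self.scheme):
            raise InvalidParameterError("4th dimension must match scheme length")
        if self.data.shape[:3] != tuple(self.geometry.shape):
            raise GeometryError("data shape does not match geometry")

    def to_nifti(self, path) -> None:
        _nifti_roundtrip(self.data, self.geometry).to_filename(str(path))

    @classmethod
    def from_nifti(cls, path, scheme: GradientScheme) -> "DWISeries":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        geom = Geometry(data.shape[:3], tuple(float(z) for z in img.header.get_zooms()[:3]),
                        np.asarray(img.affine))
        return cls(data, geom, scheme)


# Symmetric tensor component order used throughout: xx, yy, zz, xy, xz, yz.
_TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor, stored as 6 unique components."""

    components: np.ndarray  # (X, Y, Z, 6) in order xx, yy, zz, xy, xz, yz
    geometry: Geometry

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != tuple(self.geometry.shape) + (6,):
            raise GeometryError("tensor component array shape mismatch")

    def as_matrices(self) -> np.ndarray:
        """Full symmetric 3x3 matrices, shape (X, Y, Z, 3, 3)."""
        m = np.zeros(self.components.shape[:-1] + (3, 3))
        for c, (i, j) in enumerate(_TENSOR_IDX):
            m[..., i, j] = self.components[..., c]
            m[..., j, i] = self.components[..., c]
        return m

    @classmethod
    def from_matrices(cls, mats: np.ndarray, geometry: Geometry) -> "TensorVolume":
        mats = np.asarray(mats, dtype=float)
        comps = np.stack([mats[..., i, j] for (i, j) in _TENSOR_IDX], axis=-1)
        return cls(comps, geometry)


@dataclass
class FAVolume:
    """Fractional anisotropy map with an explicit validity mask.

    Masked-out voxels are distinct from FA == 0: `mask` is False there and
    `data` holds NaN.
    """

    data: np.ndarray
    geometry: Geometry
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != tuple(self.geometry.shape):
            raise GeometryError("FA map shape mismatch")
        valid = self.data[self.mask]
        if valid.size and (np.nanmin(valid) < -1e-9 or np.nanmax(valid) > 1 + 1e-9):
            raise InvalidParameterError("FA values outside [0, 1]")

    def filled(self, fill: float = 0.0) -> np.ndarray:
        out = np.where(self.mask, self.data, fill)
        return out

    def to_nifti(self, path) -> None:
        _nifti_roundtrip(self.filled(0.0), self.geometry).to_filename(str(path))


@dataclass
class LabelVolume:
    """Integer label map (FreeSurfer-style region IDs; 0 = background)."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InvalidParameterError("label volume must be integer typed")
        if self.data.shape != tuple(self.geometry.shape):
            raise GeometryError("label map shape mismatch")

    def mask_for(self, label: int) -> np.ndarray:
        return self.data == label

    def to_nifti(self, path) -> None:
        _nifti_roundtrip(self.data.astype(np.int16), self.geometry).to_filename(str(path))

    @classmethod
    def from_nifti(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.int32)
        geom = Geometry(data.shape, tuple(float(z) for z in img.header.get_zooms()[:3]),
                        np.asarray(img.affine))
        return cls(data, geom)
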