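"""Reading and writing of diffusion datasets, gradient tables, affine
transforms and deformation fields.

Conventions used throughout the package:

* voxel indices are 0-based; world coordinates (mm) are obtained through the
  NIfTI header affine;
* transforms and displacement fields are expressed in world millimetres;
* gradient vectors follow the FSL bvec convention (3 rows x m columns,
  image-axis frame) and are re-normalized on load;
* a volume is flagged b0 when its b-value falls below ``b0_threshold``
  (default 50 s/mm^2, tolerant of vendor jitter).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIDataset",
    "AffineTransform",
    "DeformationField",
    "FormatError",
    "read_dwi",
    "write_dwi",
    "read_affine",
    "write_affine",
    "read_field",
    "write_field",
]

DEFAULT_B0_THRESHOLD = 50.0  # s/mm^2


class FormatError(ValueError):
    """Malformed or inconsistent on-disk data."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: unit directions and b-values.

    Parameters
    ----------
    directions : (m, 3) array
        Gradient directions. Non-b0 rows are normalized to unit length on
        construction; b0 rows are ignored by all angular operations.
    bvalues : (m,) array
        Diffusion weightings in s/mm^2.
    b0_threshold : float
        b-values strictly below this flag a b0 volume.
    """

    directions: np.ndarray
    bvalues: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float).reshape(-1, 3).copy()
        bvals = np.asarray(self.bvalues, dtype=float).ravel().copy()
        if dirs.shape[0] != bvals.shape[0]:
            raise FormatError(
                f"{dirs.shape[0]} directions but {bvals.shape[0]} b-values"
            )
        b0 = bvals < self.b0_threshold
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(norms[~b0] == 0):
            raise FormatError("zero gradient vector on a diffusion-weighted volume")
        dirs[~b0] /= norms[~b0, None]
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "bvalues", bvals)

    @property
    def m(self) -> int:
        return self.directions.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues < self.b0_threshold

    @property
    def weighted_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.b0_mask)

    @property
    def n_weighted(self) -> int:
        return int(np.count_nonzero(~self.b0_mask))

    @property
    def weighted_directions(self) -> np.ndarray:
        return self.directions[~self.b0_mask]

    @property
    def weighted_bvalues(self) -> np.ndarray:
        return self.bvalues[~self.b0_mask]


@dataclass
class DWIDataset:
    """4-D diffusion-weighted dataset on a regular grid.

    ``signal`` has spatial shape (nx, ny, nz) plus one volume per gradient;
    ``affine`` maps 0-based voxel indices to world mm.
    """

    signal: np.ndarray
    affine: np.ndarray
    gradients: GradientTable

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.signal.ndim != 4:
            raise FormatError(f"signal must be 4-D, got shape {self.signal.shape}")
        if self.signal.shape[3] != self.gradients.m:
            raise FormatError(
                f"{self.signal.shape[3]} volumes but gradient table has "
                f"{self.gradients.m} entries"
            )
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("non-finite signal values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.spatial_shape))

    @property
    def s0(self) -> np.ndarray:
        """Mean of the b0 volumes (3-D grid)."""
        b0 = self.gradients.b0_mask
        if not np.any(b0):
            raise FormatError("dataset has no b0 volume")
        return self.signal[..., b0].mean(axis=3)

    @property
    def i_max(self) -> float:
        m = float(self.signal.max())
        if not np.isfinite(m) or m <= 0:
            raise FormatError("maximum intensity must be finite and positive")
        return m

    @property
    def voxel_size(self) -> np.ndarray:
        """Length of each voxel axis in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def copy_with(self, **kw) -> "DWIDataset":
        out = {"signal": self.signal, "affine": self.affine, "gradients": self.gradients}
        out.update(kw)
        return DWIDataset(**out)


@dataclass(frozen=True)
class AffineTransform:
    """4x4 homogeneous transform in world mm, orientation preserving."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(4, 4).copy()
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
            raise FormatError("last row of an affine transform must be [0 0 0 1]")
        if np.linalg.det(m[:3, :3]) <= 0:
            raise FormatError("affine transform must have det(linear) > 0")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_linear(cls, linear, translation=(0.0, 0.0, 0.0)) -> "AffineTransform":
        m = np.eye(4)
        m[:3, :3] = linear
        m[:3, 3] = translation
        return cls(m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self applied after other."""
        return AffineTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation


@dataclass
class DeformationField:
    """Dense displacement field u(x) in mm, sampled on a reference grid."""

    displacement: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise FormatError(
                f"displacement must have shape (nx, ny, nz, 3), got "
                f"{self.displacement.shape}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise FormatError("non-finite displacement values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]


# ---------------------------------------------------------------------------
# on-disk formats


def read_dwi(
    image_path,
    bvec_path,
    bval_path,
    b0_threshold: float = DEFAULT_B0_THRESHOLD,
) -> DWIDataset:
    """Load a 4-D NIfTI plus FSL-style bvec/bval files."""
    img = nib.load(str(image_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    bvecs = np.atleast_2d(np.loadtxt(str(bvec_path), dtype=float))
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:
            bvecs = bvecs.T
        else:
            raise FormatError(f"{bvec_path}: bvec file must have 3 rows")
    bvals = np.loadtxt(str(bval_path), dtype=float).ravel()
    if bvecs.shape[1] != data.shape[3] or bvals.size != data.shape[3]:
        raise FormatError(
            f"image has {data.shape[3]} volumes, bvec has {bvecs.shape[1]} "
            f"columns, bval has {bvals.size} entries"
        )
    table = GradientTable(bvecs.T, bvals, b0_threshold=b0_threshold)
    if table.n_weighted == 0:
        raise FormatError("gradient table contains only b0 volumes")
    return DWIDataset(data, img.affine, table)


def write_dwi(ds: DWIDataset, image_path, bvec_path, bval_path) -> None:
    nib.save(nib.Nifti1Image(ds.signal, ds.affine), str(image_path))
    np.savetxt(str(bvec_path), ds.gradients.directions.T, fmt="%.10f")
    np.savetxt(str(bval_path), ds.gradients.bvalues[None, :], fmt="%.6g")


def read_affine(path) -> AffineTransform:
    """Read a FLIRT-style whitespace-delimited 4x4 matrix."""
    m = np.loadtxt(str(path), dtype=float)
    if m.shape != (4, 4):
        raise FormatError(f"{path}: expected a 4x4 matrix, got shape {m.shape}")
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise FormatError(f"{path}: singular linear part")
    return AffineTransform(m)


def write_affine(t: AffineTransform, path) -> None:
    np.savetxt(str(path), t.matrix, fmt="%.12g")


def read_field(path) -> DeformationField:
    """Read a displacement field stored as a 4-D NIfTI with 3 components."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 5 and data.shape[3] == 1:  # tolerate FSL's 5-D layout
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError(
            f"{path}: expected (nx, ny, nz, 3) displacement, got {data.shape}"
        )
    return DeformationField(data, img.affine)


def write_field(f: DeformationField, path) -> None:
    nib.save(nib.Nifti1Image(f.displacement, f.affine), str(path))
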