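"""Cubic-B-spline free-form deformation model.

The displacement field is a linear superposition of tensor-product cubic
B-splines on a regular control lattice aligned with a reference grid:
u(x) = sum_k w_k B_k(x), with w_k a 3-vector of millimetre displacements per
control point.  The lattice carries two extra control points per side so
every reference voxel is fully supported by its 4x4x4 neighbourhood.

Evaluation is parameterized by reference *voxel* coordinates; displacement
values and Jacobians are in world millimetres (the Jacobian chains through
the inverse of the grid affine's linear part).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .io import DeformationField

__all__ = [
    "BSplineField",
    "cubic_bspline",
    "cubic_bspline_deriv",
    "eval_field",
    "eval_basis_support",
    "field_jacobian",
    "field_jacobian_grid",
    "basis_matrix",
    "densify",
    "fit_field_to_displacement",
]

_PAD = 2  # control points added on each side of the core lattice


def cubic_bspline(t: np.ndarray) -> np.ndarray:
    """The four cubic B-spline basis values at fractional position t in [0,1).

    Returns (..., 4): weights of control points at offsets (-1, 0, 1, 2)
    from the cell origin.  Rows sum to 1 (partition of unity).
    """
    t = np.asarray(t, dtype=float)
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


def cubic_bspline_deriv(t: np.ndarray) -> np.ndarray:
    """d/dt of the four basis values (per unit lattice coordinate)."""
    t = np.asarray(t, dtype=float)
    t2 = t * t
    return np.stack(
        [
            -((1 - t) ** 2) / 2.0,
            (9 * t2 - 12 * t) / 6.0,
            (-9 * t2 + 6 * t + 3) / 6.0,
            t2 / 2.0,
        ],
        axis=-1,
    )


@dataclass
class BSplineField:
    """Cubic-B-spline displacement field on a padded control lattice.

    Attributes
    ----------
    weights : (cx, cy, cz, 3) array
        Control-point displacements in mm (world).
    spacing_vox : (3,) array
        Knot spacing along each voxel axis, in voxels.
    grid_shape : (3,) ints
        Reference grid the lattice is aligned to.
    grid_affine : (4, 4) array
        Voxel-to-world map of the reference grid.
    """

    weights: np.ndarray
    spacing_vox: np.ndarray
    grid_shape: tuple
    grid_affine: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.spacing_vox = np.asarray(self.spacing_vox, dtype=float).reshape(3)
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.grid_affine = np.asarray(self.grid_affine, dtype=float).reshape(4, 4)
        if self.weights.shape != self.control_shape + (3,):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match lattice "
                f"{self.control_shape}"
            )

    @property
    def control_shape(self) -> tuple:
        return tuple(
            int(np.ceil((n - 1) / h)) + 1 + 2 * _PAD + 1
            for n, h in zip(self.grid_shape, self.spacing_vox)
        )

    @property
    def n_control(self) -> int:
        return int(np.prod(self.control_shape))

    @property
    def knot_spacing_mm(self) -> np.ndarray:
        vs = np.linalg.norm(self.grid_affine[:3, :3], axis=0)
        return self.spacing_vox * vs

    @classmethod
    def zeros(cls, grid_shape, grid_affine, knot_spacing_mm) -> "BSplineField":
        """Zero field with knot spacing given in mm (rounded to >= 1 voxel)."""
        grid_affine = np.asarray(grid_affine, dtype=float)
        vs = np.linalg.norm(grid_affine[:3, :3], axis=0)
        spacing_vox = np.maximum(np.asarray(knot_spacing_mm, dtype=float) / vs, 1.0)
        f = cls.__new__(cls)
        f.spacing_vox = np.broadcast_to(spacing_vox, (3,)).astype(float).copy()
        f.grid_shape = tuple(int(n) for n in grid_shape)
        f.grid_affine = grid_affine.reshape(4, 4)
        f.weights = np.zeros(f.control_shape + (3,))
        return f

    def copy(self) -> "BSplineField":
        return BSplineField(
            self.weights.copy(), self.spacing_vox, self.grid_shape, self.grid_affine
        )


def _lattice_coords(field: BSplineField, points_vox: np.ndarray):
    """Cell origin indices (N, 3) and per-axis basis inputs t (N, 3)."""
    t = points_vox / field.spacing_vox + _PAD
    i0 = np.floor(t).astype(int)
    frac = t - i0
    cs = field.control_shape
    lo = i0 - 1
    hi = i0 + 2
    if np.any(lo < 0) or np.any(hi >= np.asarray(cs)):
        raise ValueError("point outside the padded control lattice")
    return i0, frac


def _accumulate(field: BSplineField, points_vox, bx, by, bz) -> np.ndarray:
    """Sum w[i0-1+a, j0-1+b, k0-1+c] * bx[a] by[b] bz[c] over the 64 terms."""
    i0, _ = _lattice_coords(field, points_vox)
    out = np.zeros(points_vox.shape[:-1] + (3,))
    w = field.weights
    for a in range(4):
        ia = i0[..., 0] - 1 + a
        for b in range(4):
            jb = i0[..., 1] - 1 + b
            wab = bx[..., a] * by[..., b]
            for c in range(4):
                kc = i0[..., 2] - 1 + c
                out += (wab * bz[..., c])[..., None] * w[ia, jb, kc]
    return out


def eval_field(field: BSplineField, points_vox: np.ndarray) -> np.ndarray:
    """Displacements u (mm) at reference voxel coordinates (..., 3)."""
    points_vox = np.asarray(points_vox, dtype=float)
    _, frac = _lattice_coords(field, points_vox)
    bx = cubic_bspline(frac[..., 0])
    by = cubic_bspline(frac[..., 1])
    bz = cubic_bspline(frac[..., 2])
    return _accumulate(field, points_vox, bx, by, bz)


def field_jacobian(field: BSplineField, points_vox: np.ndarray) -> np.ndarray:
    """Analytic world-space Jacobians J_u = du/dx (..., 3, 3).

    Derivatives of the tensor-product basis with respect to lattice
    coordinates are chained through voxel spacing and the grid affine.
    """
    points_vox = np.asarray(points_vox, dtype=float)
    _, frac = _lattice_coords(field, points_vox)
    b = [cubic_bspline(frac[..., d]) for d in range(3)]
    db = [cubic_bspline_deriv(frac[..., d]) for d in range(3)]
    cols = []
    for d in range(3):  # derivative along voxel axis d
        fx = [db[ax] if ax == d else b[ax] for ax in range(3)]
        du = _accumulate(field, points_vox, *fx) / field.spacing_vox[d]
        cols.append(du)  # du/dvoxel_d, (..., 3)
    J_vox = np.stack(cols, axis=-1)  # (..., component, voxel axis)
    inv_lin = np.linalg.inv(field.grid_affine[:3, :3])
    return J_vox @ inv_lin


def field_jacobian_grid(field: BSplineField) -> np.ndarray:
    """Jacobians at every reference grid voxel, shape grid + (3, 3)."""
    pts = _grid_points(field.grid_shape)
    return field_jacobian(field, pts)


def eval_basis_support(field: BSplineField, point_vox):
    """Flat control indices and basis values of the <= 64 supporting splines.

    Values are non-negative and sum to 1 (partition of unity).
    """
    p = np.asarray(point_vox, dtype=float).reshape(3)
    i0, frac = _lattice_coords(field, p[None])
    i0, frac = i0[0], frac[0]
    b = [cubic_bspline(frac[d]) for d in range(3)]
    cs = field.control_shape
    idx, vals = [], []
    for a in range(4):
        for bb in range(4):
            for c in range(4):
                k = np.ravel_multi_index(
                    (i0[0] - 1 + a, i0[1] - 1 + bb, i0[2] - 1 + c), cs
                )
                idx.append(k)
                vals.append(b[0][a] * b[1][bb] * b[2][c])
    return np.asarray(idx), np.asarray(vals)


def basis_matrix(field: BSplineField, points_vox: np.ndarray) -> sparse.csr_matrix:
    """Sparse (N, s) matrix of basis values B_k at each point.

    Row i holds the 64 supporting basis values for point i; contracting
    against the flattened weights reproduces ``eval_field``.
    """
    pts = np.asarray(points_vox, dtype=float).reshape(-1, 3)
    i0, frac = _lattice_coords(field, pts)
    b = [cubic_bspline(frac[:, d]) for d in range(3)]
    N = pts.shape[0]
    cs = field.control_shape
    rows = np.repeat(np.arange(N), 64)
    cols = np.empty((N, 64), dtype=int)
    vals = np.empty((N, 64))
    q = 0
    for a in range(4):
        for bb in range(4):
            for c in range(4):
                cols[:, q] = np.ravel_multi_index(
                    (i0[:, 0] - 1 + a, i0[:, 1] - 1 + bb, i0[:, 2] - 1 + c), cs
                )
                vals[:, q] = b[0][:, a] * b[1][:, bb] * b[2][:, c]
                q += 1
    return sparse.csr_matrix(
        (vals.ravel(), (rows, cols.ravel())), shape=(N, field.n_control)
    )


def _grid_points(shape) -> np.ndarray:
    ax = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)


def densify(field: BSplineField) -> DeformationField:
    """Sample the field at every reference grid voxel for on-disk export."""
    u = eval_field(field, _grid_points(field.grid_shape))
    return DeformationField(u, field.grid_affine)


def fit_field_to_displacement(
    displacement_grid: np.ndarray,
    template: BSplineField,
    regularization: float = 1e-6,
    points_vox: np.ndarray | None = None,
) -> BSplineField:
    """Least-squares B-spline fit to sampled displacements.

    Used to transfer a field between lattice resolutions (dyadic cubic
    spline spaces nest, so projection onto a finer lattice is exact up to
    conditioning).  ``template`` supplies the target lattice geometry; the
    fit runs over all grid voxels unless ``points_vox`` restricts it (e.g.
    to a mask, with ``displacement_grid`` giving one 3-vector per point).
    ``regularization`` is Tikhonov damping relative to the mean diagonal of
    the normal matrix; it pins down control points with little or no support
    on the sample points without disturbing the interior fit.
    """
    u = np.asarray(displacement_grid, dtype=float).reshape(-1, 3)
    if points_vox is None:
        points_vox = _grid_points(template.grid_shape).reshape(-1, 3)
    B = basis_matrix(template, np.asarray(points_vox, dtype=float).reshape(-1, 3))
    BtB = (B.T @ B).tocsc()
    damp = regularization * BtB.diagonal().mean()
    lhs = BtB + damp * sparse.eye(template.n_control, format="csc")
    rhs = B.T @ u
    w = sparse.linalg.spsolve(lhs, rhs)
    out = template.copy()
    out.weights = np.asarray(w).reshape(template.control_shape + (3,))
    return out
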