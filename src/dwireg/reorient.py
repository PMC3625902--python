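"""Finite-strain rotation extraction and gradient reorientation.

An orientation-preserving affine A decomposes (polar decomposition) as
A = R S with R a proper rotation and S symmetric positive-definite strain.
Under a spatial transform, tissue microstructure reorients only through R;
the strain changes the shape of regions, not the fibre directions.  For a
non-linear deformation x -> x + u(x) the same decomposition is applied
voxelwise to the local affine I + J_u(x).
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import DeformationField, GradientTable

__all__ = [
    "polar_rotation",
    "rotate_gradients",
    "reoriented_directions",
    "local_affines",
    "local_rotations",
]


def polar_rotation(A: np.ndarray) -> np.ndarray:
    """Orthogonal polar factor of one or many 3x3 matrices.

    Computed from the SVD A = U diag(s) V^T as R = U V^T with the last
    column of U sign-flipped if needed so that det(R) = +1.  Requires
    det(A) > 0 everywhere.  Accepts (..., 3, 3) stacks.
    """
    A = np.asarray(A, dtype=float)
    if A.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) matrices")
    det = np.linalg.det(A)
    if np.any(det <= 0):
        raise ValueError("polar_rotation requires det(A) > 0")
    U, s, Vt = np.linalg.svd(A)
    if np.any(s[..., -1] < 1e-10 * s[..., 0]):
        warnings.warn("near-singular matrix in polar decomposition", RuntimeWarning)
    # det(U V^T) = sign(det A) = +1 here, so U V^T is already proper
    R = U @ Vt
    return R


def rotate_gradients(table: GradientTable, R: np.ndarray) -> GradientTable:
    """Replace each weighted direction g_j by R^T g_j; b-values unchanged.

    This is the gradient-frame counterpart of rotating the fibres by R:
    sampling rotated fibres with g_j equals sampling unrotated fibres with
    R^T g_j.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("R must be a 3x3 orthonormal matrix")
    dirs = table.directions.copy()
    w = ~table.b0_mask
    dirs[w] = dirs[w] @ R  # row-vector form of R^T g
    return GradientTable(dirs, table.bvalues, b0_threshold=table.b0_threshold)


def reoriented_directions(
    table: GradientTable, A: np.ndarray, method: str = "fs"
) -> np.ndarray:
    """Weighted directions reoriented by the affine linear part A.

    ``fs`` (default) uses the finite-strain rotation R^T g; ``norm`` is the
    A g / ||A g|| variant, offered for comparison only.
    """
    g = table.weighted_directions
    if method == "fs":
        return g @ polar_rotation(A)
    if method == "norm":
        out = g @ np.asarray(A, dtype=float).T
        return out / np.linalg.norm(out, axis=1, keepdims=True)
    raise ValueError(f"unknown reorientation method {method!r}")


def local_affines(field, grid_affine: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel local affine I + J_u(x) of a deformation model.

    For a B-spline field the Jacobian is analytic; for a dense sampled
    field, central finite differences (one-sided at the boundary) in voxel
    space are mapped to world derivatives through the grid affine.  Returns
    spatial_shape + (3, 3); warns listing voxels where det(I + J_u) <= 0.
    """
    from .bspline import BSplineField, field_jacobian_grid

    if isinstance(field, BSplineField):
        J = field_jacobian_grid(field)
    elif isinstance(field, DeformationField):
        aff = field.affine if grid_affine is None else grid_affine
        inv_lin = np.linalg.inv(np.asarray(aff, dtype=float)[:3, :3])
        grads = np.stack(
            [np.stack(np.gradient(field.displacement[..., c], axis=(0, 1, 2)), axis=-1)
             for c in range(3)],
            axis=-2,
        )  # (..., 3 comp, 3 d/dvoxel)
        J = grads @ inv_lin
    else:
        raise TypeError(f"unsupported field type {type(field)!r}")
    A = J + np.eye(3)
    det = np.linalg.det(A)
    if np.any(det <= 0):
        folded = np.argwhere(det <= 0)
        warnings.warn(
            f"deformation folds at {folded.shape[0]} voxels "
            f"(first few: {folded[:5].tolist()})",
            RuntimeWarning,
        )
    return A


def local_rotations(field, grid_affine: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise finite-strain rotation of I + J_u(x).

    Returns spatial_shape + (3, 3) proper rotations; folded voxels (where
    det(I + J_u) <= 0) fall back to the identity and should be masked by the
    caller.
    """
    A = local_affines(field, grid_affine)
    det = np.linalg.det(A)
    ok = det > 0
    R = np.broadcast_to(np.eye(3), A.shape).copy()
    if np.all(ok):
        return polar_rotation(A)
    R[ok] = polar_rotation(A[ok])
    return R
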