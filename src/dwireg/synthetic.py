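"""Ground-truth generators: multi-tensor diffusion phantoms, random affine
warps and random topology-preserving deformation fields.

The phantom signal follows the Gaussian (tensor) closed form of the
Stejskal-Tanner attenuation: for a voxel containing compartments with
tensors D_f (mm^2/s) and fractions f summing to 1,

    S(x, g_j) = S0(x) * sum_f  f * exp(-b * g_j^T D_f g_j),

with b0 volumes equal to S0(x).  Optional Rician noise uses the magnitude
convention sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2).

Random affines have the form A = R S D (rotation, unit-diagonal upper
triangular shear, diagonal scale) plus a translation; random B-spline fields
draw i.i.d. uniform control weights and are globally rescaled by bisection
until min det(I + J_u) > 0.1 on the grid (topology preservation).

``apply_ground_truth_warp(ds, T)`` returns the test image whose registration
back onto ``ds`` recovers T: the output reads the input at the pulled-back
location T(x) (T x for an affine, x + u(x) for a field) and its weighted
volumes are intensity-corrected at the locally rotated directions R g_j with
R the finite-strain rotation of the local pull-back linear part.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .bspline import BSplineField, eval_field, field_jacobian_grid
from .io import AffineTransform, DWIDataset, GradientTable
from .reorient import polar_rotation
from .sphere import AngularKernel, angular_resample, sh_basis, sh_fit

__all__ = [
    "PhantomSpec",
    "WarpSpec",
    "fibonacci_directions",
    "make_gradient_table",
    "simulate_phantom",
    "default_tensors",
    "random_affine",
    "random_field",
    "apply_ground_truth_warp",
    "add_rician_noise",
]

# typical white/gray-matter diffusivities, mm^2/s
PROLATE_X = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
PROLATE_Y = np.diag([0.3e-3, 1.7e-3, 0.3e-3])
ISOTROPIC = np.eye(3) * 0.7e-3


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit directions on the upper hemisphere."""
    i = np.arange(n) + 0.5
    z = i / n  # cos(polar), upper hemisphere
    phi = np.pi * (1 + np.sqrt(5)) * i
    s = np.sqrt(1 - z**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def make_gradient_table(
    n_directions: int = 30, n_b0: int = 3, bvalue: float = 1500.0
) -> GradientTable:
    """b0 volumes first, then a hemisphere scheme at a single shell."""
    dirs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_directions)])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bvalue)])
    return GradientTable(dirs, bvals)


@dataclass
class PhantomSpec:
    """Multi-compartment tensor phantom on a desk-scale grid.

    Defaults mirror a single-shell acquisition at toy size: 32x32x16 voxels,
    30 directions + 3 b0s at b = 1500 s/mm^2.  ``region_tensors`` maps a
    region label to a list of (fraction, 3x3 SPD tensor) compartments; if
    None, a two-region layout is used (prolate-x left, 50/50 x/y crossing
    right, inside an off-centre ellipsoid; air outside).
    """

    shape: tuple = (32, 32, 16)
    voxel_size: float = 2.0  # mm
    bvalue: float = 1500.0  # s/mm^2
    n_directions: int = 30
    n_b0: int = 3
    s0: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0
    s0_texture: bool = True
    region_labels: np.ndarray | None = None
    region_tensors: dict | None = None
    gradient_table: GradientTable | None = None


def default_tensors() -> dict:
    return {
        0: [],  # air
        1: [(1.0, ISOTROPIC)],
        2: [(1.0, PROLATE_X)],
        3: [(0.5, PROLATE_X), (0.5, PROLATE_Y)],  # crossing fibres
    }


def _default_labels(shape) -> np.ndarray:
    nx, ny, nz = shape
    i, j, k = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    # off-centre ellipsoid to break rotational symmetry
    cx, cy, cz = 0.52 * nx, 0.48 * ny, 0.5 * nz
    r2 = (
        ((i - cx) / (0.42 * nx)) ** 2
        + ((j - cy) / (0.36 * ny)) ** 2
        + ((k - cz) / (0.42 * nz)) ** 2
    )
    labels = np.zeros(shape, dtype=int)
    inside = r2 <= 1.0
    labels[inside] = 1
    labels[inside & (i < cx) & (r2 <= 0.75)] = 2
    labels[inside & (i >= cx) & (r2 <= 0.75)] = 3
    return labels


def simulate_phantom(spec: PhantomSpec | None = None, **kw) -> DWIDataset:
    """Noise-free (or Rician-noised) tensor-mixture phantom."""
    spec = spec or PhantomSpec(**kw)
    table = spec.gradient_table or make_gradient_table(
        spec.n_directions, spec.n_b0, spec.bvalue
    )
    labels = (
        spec.region_labels
        if spec.region_labels is not None
        else _default_labels(spec.shape)
    )
    tensors = spec.region_tensors if spec.region_tensors is not None else default_tensors()
    for comps in tensors.values():
        for _, D in comps:
            ev = np.linalg.eigvalsh(np.asarray(D))
            if np.any(ev <= 0) or not np.allclose(D, np.asarray(D).T):
                raise ValueError("region tensors must be symmetric positive-definite")

    shape = labels.shape
    s0_map = np.full(shape, spec.s0)
    if spec.s0_texture:
        nx, ny, nz = shape
        i, j, k = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        blob = np.exp(
            -(
                ((i - 0.38 * nx) / (0.30 * nx)) ** 2
                + ((j - 0.60 * ny) / (0.30 * ny)) ** 2
                + ((k - 0.45 * nz) / (0.35 * nz)) ** 2
            )
        )
        s0_map = spec.s0 * (0.65 + 0.55 * blob)

    g = table.directions
    b = table.bvalues
    atten = np.zeros(shape + (table.m,))
    for label, comps in tensors.items():
        sel = labels == label
        if not np.any(sel):
            continue
        if not comps:
            continue  # air: stays zero
        frac = np.array([f for f, _ in comps])
        if not np.isclose(frac.sum(), 1.0):
            raise ValueError("compartment fractions must sum to 1")
        a = np.zeros(table.m)
        for f, D in comps:
            a += f * np.exp(-b * np.einsum("ja,ab,jb->j", g, np.asarray(D), g))
        a[table.b0_mask] = 1.0
        atten[sel] = a
    signal = s0_map[..., None] * atten
    aff = np.diag([spec.voxel_size] * 3 + [1.0])
    ds = DWIDataset(signal, aff, table)
    if spec.noise_sigma > 0:
        ds = add_rician_noise(ds, spec.noise_sigma, spec.seed)
    return ds


def add_rician_noise(ds: DWIDataset, sigma: float, seed: int = 0) -> DWIDataset:
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, ds.signal.shape)
    n2 = rng.normal(0.0, sigma, ds.signal.shape)
    noisy = np.sqrt((ds.signal + n1) ** 2 + n2**2)
    return ds.copy_with(signal=noisy)


# ---------------------------------------------------------------------------
# random warps


@dataclass
class WarpSpec:
    """Ranges for random affine (A = RSD + t) and B-spline field generation."""

    max_rotation_deg: float = 12.0
    min_rotation_deg: float = 0.0
    max_translation_mm: float = 4.0
    max_shear: float = 0.0
    scale_range: tuple = (1.0, 1.0)
    field_amplitude_mm: float = 6.0
    field_knot_spacing_mm: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_range[0] <= 0:
            raise ValueError("scales must stay positive to keep det(A) > 0")


def _random_rotation(rng: np.random.Generator, max_deg: float, min_deg: float = 0.0) -> np.ndarray:
    if max_deg == 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(min_deg, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def random_affine(spec: WarpSpec) -> AffineTransform:
    """Random A = R S D with translation; deterministic per seed; det > 0."""
    rng = np.random.default_rng(spec.seed)
    R = _random_rotation(rng, spec.max_rotation_deg, spec.min_rotation_deg)
    S = np.eye(3)
    iu = np.triu_indices(3, k=1)
    S[iu] = rng.uniform(-spec.max_shear, spec.max_shear, size=3)
    D = np.diag(rng.uniform(*spec.scale_range, size=3))
    t = rng.uniform(-spec.max_translation_mm, spec.max_translation_mm, size=3)
    return AffineTransform.from_linear(R @ S @ D, t)


def random_field(
    spec: WarpSpec, grid_shape, grid_affine, det_floor: float = 0.1
) -> BSplineField:
    """Random topology-preserving B-spline field on the reference grid.

    Control weights are i.i.d. uniform in +/- ``field_amplitude_mm`` and the
    whole field is rescaled by bisection until min det(I + J_u) on the grid
    exceeds ``det_floor`` (amplitude -> 0 gives the identity, so a feasible
    scale always exists).
    """
    rng = np.random.default_rng(spec.seed)
    f = BSplineField.zeros(grid_shape, grid_affine, spec.field_knot_spacing_mm)
    base = rng.uniform(
        -spec.field_amplitude_mm, spec.field_amplitude_mm, size=f.weights.shape
    )

    def min_det(scale: float) -> float:
        f.weights = scale * base
        J = field_jacobian_grid(f)
        return float(np.linalg.det(J + np.eye(3)).min())

    if min_det(1.0) > det_floor:
        return f
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if min_det(mid) > det_floor:
            lo = mid
        else:
            hi = mid
    assert min_det(lo) > det_floor
    return f


# ---------------------------------------------------------------------------
# ground-truth warping


def _warp_volumes(ds: DWIDataset, coords_vox: np.ndarray, order: int = 3) -> np.ndarray:
    out = np.empty(coords_vox.shape[1:] + (ds.signal.shape[3],))
    for j in range(ds.signal.shape[3]):
        out[..., j] = ndimage.map_coordinates(
            ds.signal[..., j], coords_vox, order=order, mode="constant", cval=0.0
        )
    return out


def apply_ground_truth_warp(
    ds: DWIDataset,
    warp,
    intensity_correction: str = "sh",
    kernel: AngularKernel | None = None,
    sh_order: int = 8,
) -> DWIDataset:
    """Warp a dataset by a known transform with optional intensity correction.

    ``warp`` is an :class:`AffineTransform` or :class:`BSplineField`.  The
    output at voxel x reads the input at the pulled-back point (A x, or
    x + u(x)), so registering the output back onto ``ds`` recovers ``warp``.
    ``intensity_correction`` is ``"sh"`` (order-8 spherical harmonics, the
    unbiased protocol), ``"ai"`` (angular interpolation) or ``"none"``
    (spatial warping only, which leaves the fibre orientations inconsistent
    for anisotropic tissue).
    """
    if intensity_correction not in ("sh", "ai", "none"):
        raise ValueError(f"unknown intensity correction {intensity_correction!r}")
    shape = ds.spatial_shape
    ax = [np.arange(n, dtype=float) for n in shape]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=0)  # (3, ...)
    inv_aff = np.linalg.inv(ds.affine)

    if isinstance(warp, AffineTransform):
        M = inv_aff @ warp.matrix @ ds.affine
        coords = np.einsum("ab,b...->a...", M[:3, :3], grid) + M[:3, 3, None, None, None]
        R_global = polar_rotation(warp.linear)
        rotations = None
    elif isinstance(warp, BSplineField):
        pts = np.moveaxis(grid, 0, -1)
        u = eval_field(warp, pts)  # mm
        world = np.einsum("ab,...b->...a", ds.affine[:3, :3], pts) + ds.affine[:3, 3]
        y = world + u
        vox = np.einsum("ab,...b->...a", inv_aff[:3, :3], y) + inv_aff[:3, 3]
        coords = np.moveaxis(vox, -1, 0)
        from .reorient import local_rotations

        rotations = local_rotations(warp)
        R_global = None
    else:
        raise TypeError(f"unsupported warp type {type(warp)!r}")

    table = ds.gradients
    widx = table.weighted_indices
    warped = _warp_volumes(ds, coords)

    if intensity_correction == "none":
        return ds.copy_with(signal=warped)

    if intensity_correction == "ai":
        tmp = ds.copy_with(signal=warped)
        if R_global is not None:
            targets = table.weighted_directions @ R_global.T  # rows are R g_j
            sig = angular_resample(tmp, targets=targets, kernel=kernel)
        else:
            sig = angular_resample(tmp, rotations=rotations, kernel=kernel)
        return ds.copy_with(signal=sig)

    # SH: fit on the unwarped data, warp the coefficient volumes spatially,
    # evaluate at the locally rotated directions
    coeffs = sh_fit(ds, order=sh_order)
    warped_coeffs = np.empty(shape + (coeffs.shape[-1],))
    for c in range(coeffs.shape[-1]):
        warped_coeffs[..., c] = ndimage.map_coordinates(
            coeffs[..., c], coords, order=3, mode="constant", cval=0.0
        )
    out = warped.copy()
    g = table.weighted_directions
    if R_global is not None:
        basis = sh_basis(sh_order, g @ R_global.T)  # (mw, ncoef)
        out[..., widx] = warped_coeffs @ basis.T
    else:
        tgt = np.einsum("...ab,jb->...ja", rotations, g)  # (..., mw, 3)
        basis = sh_basis(sh_order, tgt.reshape(-1, 3)).reshape(
            shape + (len(widx), -1)
        )
        out[..., widx] = np.einsum("...jc,...c->...j", basis, warped_coeffs)
    return ds.copy_with(signal=out)
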