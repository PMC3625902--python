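"""Affine registration of diffusion-weighted datasets with angular
interpolation.

The cost compares the reference with the test image pulled back through
A^-1 and angularly corrected at every evaluation: the weighted volumes are
resampled at the reoriented directions R^T g_j, where R is the finite-strain
rotation of A.  Minimization is derivative-free (Powell) inside a
coarse-to-fine pyramid, which satisfies the monotone accepted-cost contract
without requiring derivatives of the angular correction.

Transforms are parameterized as a perturbation composed with the initial
transform: rotations (Euler xyz, radians), translations (mm), log-scales,
shears (in that order), with the linear part built as R * Shear * Scale
about the world centre of the reference grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .io import AffineTransform, DWIDataset
from .report import RegistrationReport
from .reorient import polar_rotation
from .sphere import AngularKernel, angular_resample

__all__ = [
    "AffineSearchConfig",
    "params_to_transform",
    "resample_spatial",
    "ai_correct_affine",
    "cost_affine",
    "register_affine",
]


@dataclass
class AffineSearchConfig:
    metric: str = "cc"  # "ssd" or "cc" (1 - normalized cross-correlation)
    dof: int = 6  # 6 rigid, 9 +scales, 12 +shears
    pyramid_levels: int = 2  # downsampling factors 2**(level-1), ..., 1
    max_iter: int = 5  # Powell iterations per level
    xtol: float = 1e-3
    ftol: float = 1e-7
    interp_order: int = 1
    mask_fraction: float = 0.05  # of max reference s0
    use_ai: bool = True  # disable for spatial-only (volumes-style) runs
    multi_start_deg: float = 6.0  # coarse-level rotation perturbation starts
    min_overlap: int = 32  # voxels

    def __post_init__(self) -> None:
        if self.metric not in ("ssd", "cc"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.dof not in (6, 9, 12):
            raise ValueError("dof must be 6, 9 or 12")


# parameter scaling so Powell's unit initial steps are sensible
_SCALES = np.array([0.05, 0.05, 0.05, 1.0, 1.0, 1.0, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02])


def _euler_xyz(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def params_to_transform(params: np.ndarray, center=(0.0, 0.0, 0.0)) -> AffineTransform:
    """Build a world-space transform from up to 12 parameters.

    Order: 3 Euler rotations (xyz, rad), 3 translations (mm), 3 log-scales,
    3 shears (xy, xz, yz).  The linear map acts about ``center``:
    x' = L (x - c) + c + t.
    """
    p = np.zeros(12)
    p[: len(params)] = params
    R = _euler_xyz(*p[:3])
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = p[9], p[10], p[11]
    L = R @ shear @ np.diag(np.exp(p[6:9]))
    c = np.asarray(center, dtype=float)
    t = p[3:6] + c - L @ c
    return AffineTransform.from_linear(L, t)


def resample_spatial(
    ds: DWIDataset,
    transform: AffineTransform,
    reference: DWIDataset | tuple,
    order: int = 1,
):
    """Pull the test image back onto a reference grid.

    Output voxel i reads the test image at A^-1 x_i (world).  Every volume
    uses the same spatial map.  Returns ``(signal, valid)`` where ``valid``
    marks voxels whose pull-back lands inside the test field of view
    (out-of-field voxels are zero).
    """
    if isinstance(reference, DWIDataset):
        ref_shape, ref_affine = reference.spatial_shape, reference.affine
    else:
        ref_shape, ref_affine = reference
    # ref voxel -> ref world -> A^-1 -> test world -> test voxel
    M = np.linalg.inv(ds.affine) @ np.linalg.inv(transform.matrix) @ np.asarray(ref_affine)
    ax = [np.arange(n, dtype=float) for n in ref_shape]
    grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=0)  # (3, nx, ny, nz)
    coords = np.einsum("ab,b...->a...", M[:3, :3], grid) + M[:3, 3, None, None, None]
    shp = np.asarray(ds.spatial_shape, dtype=float)
    valid = np.all(
        (coords >= -0.5) & (coords <= (shp - 0.5)[:, None, None, None]), axis=0
    )
    m = ds.signal.shape[3]
    out = np.empty(tuple(ref_shape) + (m,))
    for j in range(m):
        out[..., j] = ndimage.map_coordinates(
            ds.signal[..., j], coords, order=order, mode="constant", cval=0.0
        )
    return out, valid


def ai_correct_affine(
    signal: np.ndarray,
    ds_like: DWIDataset,
    transform: AffineTransform,
    kernel: AngularKernel | None = None,
) -> np.ndarray:
    """Angular correction of a spatially resampled signal for transform A.

    The pull-back through A^-1 carries rotation polar(A^-1) = R^T with
    R = polar(A), so the weighted volumes are resampled at targets R^T g_j.
    A pure translation (R = I) leaves the signal untouched (snap path).
    """
    R = polar_rotation(transform.linear)
    table = ds_like.gradients
    targets = table.weighted_directions @ R  # rows are R^T g_j
    tmp = DWIDataset(signal, ds_like.affine, table)
    return angular_resample(tmp, targets=targets, kernel=kernel)


def _metric(ref_sig, test_sig, mask, metric: str) -> float:
    a = ref_sig[mask]  # (n_mask, m)
    b = test_sig[mask]
    if metric == "ssd":
        return float(np.mean((a - b) ** 2))
    # per-volume normalized cross-correlation, averaged
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt((ac**2).sum(axis=0) * (bc**2).sum(axis=0))
    denom = np.where(denom > 0, denom, 1.0)
    cc = (ac * bc).sum(axis=0) / denom
    return float(1.0 - cc.mean())


def cost_affine(
    ref: DWIDataset,
    test: DWIDataset,
    transform: AffineTransform,
    config: AffineSearchConfig | None = None,
    kernel: AngularKernel | None = None,
) -> float:
    """Dissimilarity between ref and the warped-and-corrected test image.

    Requires the two datasets to share a gradient table (match them first
    with :func:`dwireg.sphere.match_gradient_tables` otherwise).
    """
    config = config or AffineSearchConfig()
    sig, valid = resample_spatial(test, transform, ref, order=config.interp_order)
    mask = valid & (ref.s0 > config.mask_fraction * ref.s0.max())
    # restrict to the warped test's own support as well: the test image may
    # carry zero-filled out-of-field regions from an earlier resampling
    test_s0 = sig[..., test.gradients.b0_mask].mean(axis=-1)
    if test_s0.max() > 0:
        mask &= test_s0 > config.mask_fraction * test_s0.max()
    if mask.sum() < config.min_overlap:
        raise ValueError("degenerate overlap between warped test and reference")
    if config.use_ai:
        sig = ai_correct_affine(sig, ref, transform, kernel)
    return _metric(ref.signal, sig, mask, config.metric)


def _downsample(ds: DWIDataset, factor: int) -> DWIDataset:
    if factor == 1:
        return ds
    sig = ndimage.gaussian_filter(
        ds.signal, sigma=[factor / 2.0] * 3 + [0.0], mode="nearest"
    )
    sig = sig[::factor, ::factor, ::factor]
    aff = ds.affine @ np.diag([factor, factor, factor, 1.0])
    return DWIDataset(sig, aff, ds.gradients)


def register_affine(
    ref: DWIDataset,
    test: DWIDataset,
    config: AffineSearchConfig | None = None,
    initial: AffineTransform | None = None,
    kernel: AngularKernel | None = None,
):
    """Estimate the affine transform registering test to ref.

    Powell search over a perturbation of ``initial`` within a coarse-to-fine
    pyramid; the angular correction is re-applied from the full current
    transform at every cost evaluation.  Returns ``(transform, report)``;
    the report's cost trace is the running best (accepted) cost, hence
    non-increasing.
    """
    config = config or AffineSearchConfig()
    initial = initial or AffineTransform.identity()
    nparams = config.dof
    center = (ref.affine @ np.append(np.asarray(ref.spatial_shape) / 2.0, 1.0))[:3]

    report = RegistrationReport()
    p = np.zeros(nparams)

    for level in range(config.pyramid_levels - 1, -1, -1):
        factor = 2**level
        ref_l = _downsample(ref, factor)
        test_l = _downsample(test, factor)
        trace: list[float] = []

        def cost_of(p_scaled: np.ndarray) -> float:
            t = params_to_transform(p_scaled * _SCALES[:nparams], center)
            try:
                c = cost_affine(ref_l, test_l, t.compose(initial), config, kernel)
            except ValueError:
                return 1e6  # degenerate overlap: reject region
            trace.append(c)
            return c

        x0 = p / _SCALES[:nparams]
        if level == config.pyramid_levels - 1 and config.multi_start_deg > 0:
            # cheap multi-start: perturb each rotation axis at the coarsest level
            starts = [x0]
            d = np.deg2rad(config.multi_start_deg) / _SCALES[0]
            for axis in range(3):
                for sgn in (1, -1):
                    s = x0.copy()
                    s[axis] += sgn * d
                    starts.append(s)
            x0 = min(starts, key=cost_of)
        res = optimize.minimize(
            cost_of,
            x0,
            method="Powell",
            options={
                "maxiter": config.max_iter,
                "xtol": config.xtol,
                "ftol": config.ftol,
            },
        )
        p = res.x * _SCALES[:nparams]
        if not res.success and "maxiter" not in str(res.message).lower():
            report.warnings.append(f"level {level}: {res.message}")
        accepted = np.minimum.accumulate(trace) if trace else []
        report.level_breaks.append(len(report.cost_trace))
        report.cost_trace.extend(accepted)
        report.final_cost = float(res.fun)

    final = params_to_transform(p, center).compose(initial)
    report.converged = not report.warnings
    report.extras["parameters"] = [float(v) for v in p]
    return final, report
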