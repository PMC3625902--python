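"""Gauss-Newton/LM non-linear registration with per-voxel angular correction."""

import numpy as np

from dwireg.bspline import BSplineField, eval_field
from dwireg.io import DWIDataset, GradientTable
from dwireg.nonlinear import (
    GaussNewtonState,
    NonlinearConfig,
    _Problem,
    gn_step,
    register_nonlinear,
    residual_jacobian,
    warp_and_correct,
)
from dwireg.synthetic import PhantomSpec, apply_ground_truth_warp, simulate_phantom

from conftest import rotation_about_z


def _grid_pts(shape):
    ax = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)


def test_warp_and_correct_zero_field_is_identity(small_phantom):
    f = BSplineField.zeros(small_phantom.spatial_shape, small_phantom.affine, 16.0)
    sig, n_fold = warp_and_correct(small_phantom, f)
    assert n_fold == 0
    # identical up to cubic-spline prefilter roundoff
    np.testing.assert_allclose(sig, small_phantom.signal, atol=1e-5 * small_phantom.i_max)


def test_warp_and_correct_rigid_on_isotropic_equals_spatial_only():
    iso = simulate_phantom(
        PhantomSpec(shape=(10, 10, 6), region_labels=np.ones((10, 10, 6), int))
    )
    from dwireg.bspline import fit_field_to_displacement

    R = rotation_about_z(10.0)
    world = _grid_pts(iso.spatial_shape) * 2.0
    u = world @ (R - np.eye(3)).T
    f = fit_field_to_displacement(
        u, BSplineField.zeros(iso.spatial_shape, iso.affine, 8.0), regularization=1e-10
    )
    with_ai, _ = warp_and_correct(iso, f, use_ai=True)
    spatial, _ = warp_and_correct(iso, f, use_ai=False)
    np.testing.assert_allclose(with_ai, spatial, atol=1e-8)


def test_warp_and_correct_rigid_on_prolate_matches_rotated_tensor():
    """A B-spline field reproducing a rigid motion must angularly correct a
    single-tensor phantom toward the rotated-tensor closed form."""
    from dwireg.bspline import fit_field_to_displacement
    from dwireg.synthetic import PROLATE_X

    ds = simulate_phantom(
        PhantomSpec(
            shape=(12, 12, 6),
            n_directions=64,
            region_labels=np.full((12, 12, 6), 2),
            s0_texture=False,
        )
    )
    R = rotation_about_z(15.0)
    shape = np.array(ds.spatial_shape, dtype=float)
    center = (shape / 2.0) * 2.0
    world = _grid_pts(ds.spatial_shape) * 2.0
    u = (world - center) @ (R - np.eye(3)).T
    f = fit_field_to_displacement(
        u, BSplineField.zeros(ds.spatial_shape, ds.affine, 8.0), regularization=1e-10
    )
    sig, _ = warp_and_correct(ds, f, use_ai=True)
    # interior voxels: compare against the closed form at directions R g
    tgt = ds.gradients.weighted_directions @ R.T
    analytic = ds.signal[0, 0, 0, 0] * np.exp(
        -1500.0 * np.einsum("ja,ab,jb->j", tgt, PROLATE_X, tgt)
    )
    got = sig[6, 6, 3, ds.gradients.weighted_indices]
    assert (np.abs(got - analytic) / analytic).mean() < 0.06


def test_constant_image_gives_zero_jacobian_and_zero_step():
    table = GradientTable([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                           [0.7071, 0.7071, 0], [0.7071, 0, 0.7071], [0, 0.7071, 0.7071]],
                          [0.0] + [1000.0] * 6)
    sig = np.full((8, 8, 4, 7), 10.0)
    ds = DWIDataset(sig, np.diag([2.0, 2, 2, 1]), table)
    f = BSplineField.zeros(ds.spatial_shape, ds.affine, 8.0)
    E, jblocks = residual_jacobian(ds, ds, f)
    # flat up to spline-prefilter roundoff on the constant value 10
    assert np.abs(E).max() < 1e-3
    assert max(np.abs(j).max() for j in jblocks) < 1e-3


def test_zero_residual_gives_zero_gradient(isotropic_smooth_phantom):
    ds = isotropic_smooth_phantom
    f = BSplineField.zeros(ds.spatial_shape, ds.affine, 8.0)
    prob = _Problem(ds, ds, f, NonlinearConfig(), None)
    state, _ = prob.assemble(f.weights)
    assert state.C < 1e-10 * ds.i_max**2  # zero up to interpolation roundoff
    np.testing.assert_allclose(state.gradient, 0.0, atol=1e-2)
    # the proposed update stays far below the voxel scale (weakly supported
    # lattice directions amplify the roundoff gradient, bounded by damping)
    assert np.abs(gn_step(state)).max() < 0.1 * 2.0  # mm


def test_gn_step_exact_on_quadratic():
    """Newton with analytic H and gradient minimizes a quadratic in one
    undamped step: C(w) = (w - 2)^2 per component."""
    w = np.zeros((1, 1, 1, 3))
    H = 2.0 * np.eye(3)
    grad = 2.0 * (w.ravel() - 2.0)
    state = GaussNewtonState(w=w, E=np.zeros((1, 1)), C=12.0, gradient=grad,
                             H=H, lm_lambda=0.0)
    step = gn_step(state)
    np.testing.assert_allclose(w + step, 2.0, atol=1e-10)


def test_gradient_matches_finite_differences(isotropic_smooth_phantom):
    """Assembled grad C vs central differences of C in random directions.

    On an isotropic phantom the angular correction is exactly constant in w,
    so the neglected correction derivative vanishes and the assembled
    gradient must match the true derivative of the smooth interpolated cost.
    """
    ds = isotropic_smooth_phantom
    rng = np.random.default_rng(1)
    f0 = BSplineField.zeros(ds.spatial_shape, ds.affine, 8.0)
    f0.weights = rng.uniform(-1, 1, f0.weights.shape)
    test = apply_ground_truth_warp(ds, f0, intensity_correction="ai")
    field = BSplineField.zeros(ds.spatial_shape, ds.affine, 8.0)
    prob = _Problem(ds, test, field, NonlinearConfig(), None)
    w0 = rng.uniform(-0.5, 0.5, field.weights.shape)
    state, _ = prob.assemble(w0)
    for _ in range(10):
        d = rng.normal(size=state.gradient.shape)
        d /= np.linalg.norm(d)
        eps = 1e-3
        dw = (d.reshape(3, -1).T * eps).reshape(w0.shape)
        fd = (prob.cost(w0 + dw) - prob.cost(w0 - dw)) / (2 * eps)
        assert abs(fd - state.gradient @ d) / abs(fd) < 1e-3


def test_hessian_symmetric_psd(isotropic_smooth_phantom):
    ds = isotropic_smooth_phantom
    rng = np.random.default_rng(2)
    field = BSplineField.zeros(ds.spatial_shape, ds.affine, 8.0)
    w = rng.uniform(-0.5, 0.5, field.weights.shape)
    prob = _Problem(ds, ds, field, NonlinearConfig(), None)
    state, _ = prob.assemble(w)
    np.testing.assert_allclose(state.H, state.H.T, atol=1e-10)
    ev = np.linalg.eigvalsh(state.H)
    assert ev.min() >= -1e-8 * np.trace(state.H)


def test_first_order_prediction_of_cost_change(isotropic_smooth_phantom):
    """J predicts the first-order change of C for single-coefficient moves."""
    ds = isotropic_smooth_phantom
    rng = np.random.default_rng(3)
    f0 = BSplineField.zeros(ds.spatial_shape, ds.affine, 8.0)
    f0.weights = rng.uniform(-1, 1, f0.weights.shape)
    test = apply_ground_truth_warp(ds, f0, intensity_correction="none")
    field = BSplineField.zeros(ds.spatial_shape, ds.affine, 8.0)
    prob = _Problem(ds, test, field, NonlinearConfig(), None)
    w0 = np.zeros(field.weights.shape)
    state, _ = prob.assemble(w0)
    n3 = state.gradient.size
    for k in rng.choice(n3, size=10, replace=False):
        eps = 1e-2
        dw = np.zeros(n3)
        dw[k] = eps
        actual = prob.cost(w0 + dw.reshape(3, -1).T.reshape(w0.shape)) - state.C
        predicted = state.gradient[k] * eps
        assert abs(actual - predicted) <= 5e-3 * max(abs(actual), 1e-8) + 1e-4 * eps


def test_self_registration_returns_near_zero_field(small_phantom):
    cfg = NonlinearConfig(knot_spacing_mm=16.0, levels=1, max_iter=3)
    field, report = register_nonlinear(small_phantom, small_phantom, cfg)
    u = eval_field(field, _grid_pts(small_phantom.spatial_shape))
    rms_vox = np.sqrt((np.linalg.norm(u, axis=-1) ** 2).mean()) / 2.0
    assert rms_vox < 0.1
    assert report.extras["folded_voxels"] == 0


def test_scalar_degenerate_case_reduces_to_single_volume_registration():
    """With one weighted volume and AI disabled the machinery is plain
    scalar-image B-spline registration and still recovers a displacement."""
    rng = np.random.default_rng(4)
    table = GradientTable([[0, 0, 0], [1, 0, 0]], [0.0, 1000.0])
    base = simulate_phantom(PhantomSpec(shape=(12, 12, 6)))
    sig = np.stack([base.s0, 0.6 * base.s0], axis=-1)
    ds = DWIDataset(sig, base.affine, table)
    f0 = BSplineField.zeros(ds.spatial_shape, ds.affine, 12.0)
    f0.weights = rng.uniform(-2, 2, f0.weights.shape)
    test = apply_ground_truth_warp(ds, f0, intensity_correction="none")
    cfg = NonlinearConfig(knot_spacing_mm=12.0, levels=1, max_iter=6, use_ai=False)
    field, report = register_nonlinear(ds, test, cfg)
    trace = np.array(report.cost_trace)
    assert trace[-1] < 0.5 * trace[0]
    assert np.all(np.diff(trace) < 0)
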