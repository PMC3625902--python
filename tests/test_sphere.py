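"""Angular interpolation and spherical-harmonics resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwireg.io import GradientTable
from dwireg.sphere import (
    angular_resample,
    angular_weights,
    geodesic_angle,
    match_gradient_tables,
    n_sh_coefficients,
    sh_basis,
    sh_eval,
    sh_fit,
)
from dwireg.synthetic import PROLATE_X, PhantomSpec, simulate_phantom

from conftest import rotation_about_z

EX, EY = np.array([1.0, 0, 0]), np.array([0.0, 1, 0])


@pytest.mark.parametrize(
    "g1,g2,expected",
    [(EX, EX, 0.0), (EX, -EX, 0.0), (EX, EY, np.pi / 2)],
)
def test_geodesic_angle_known_pairs(g1, g2, expected):
    assert geodesic_angle(g1, g2) == pytest.approx(expected, abs=1e-12)
    assert geodesic_angle(g2, g1) == pytest.approx(expected, abs=1e-12)


def test_geodesic_angle_rejects_non_unit():
    with pytest.raises(ValueError):
        geodesic_angle(np.zeros(3), EX)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_weights_normalized_and_sign_invariant(seed):
    rng = np.random.default_rng(seed)
    d = rng.normal(size=(20, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    table = GradientTable(d, np.full(20, 1000.0))
    t = rng.normal(size=3)
    t /= np.linalg.norm(t)
    w = angular_weights(t, table)
    assert w.min() >= 0
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    # antipodal invariance of the target
    np.testing.assert_allclose(angular_weights(-t, table), w, atol=1e-12)


def test_weights_snap_and_symmetry(small_phantom):
    table = small_phantom.gradients
    w = angular_weights(table.directions[5], table)
    expected = np.zeros(table.m)
    expected[5] = 1.0
    np.testing.assert_array_equal(w, expected)
    # b0 volumes never receive weight
    assert w[table.b0_mask].sum() == 0.0

    # target equidistant from two directions, all others far away
    d = np.array([[1.0, 0, 0], [0.0, 1, 0], [0.0, 0, 1]])
    t2 = GradientTable(d, np.full(3, 1000.0))
    mid = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    w2 = angular_weights(mid, t2)
    assert w2[0] == pytest.approx(w2[1], abs=1e-12)


def test_resample_at_own_directions_is_identity(small_phantom):
    out = angular_resample(
        small_phantom, targets=small_phantom.gradients.weighted_directions
    )
    np.testing.assert_array_equal(out, small_phantom.signal)


def test_resample_constant_signal_invariant(small_phantom):
    table = small_phantom.gradients
    sig = small_phantom.signal.copy()
    sig[..., ~table.b0_mask] = 7.0
    ds = small_phantom.copy_with(signal=sig)
    rng = np.random.default_rng(3)
    t = rng.normal(size=(table.n_weighted, 3))
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    out = angular_resample(ds, targets=t)
    np.testing.assert_allclose(out[..., ~table.b0_mask], 7.0, atol=1e-12)


def test_resample_rotated_matches_analytic_tensor(prolate_phantom64):
    ds = prolate_phantom64
    R = rotation_about_z(30.0)
    tgt = ds.gradients.weighted_directions @ R.T
    out = angular_resample(ds, targets=tgt)
    analytic = ds.signal[0, 0, 0, 0] * np.exp(
        -1500.0 * np.einsum("ja,ab,jb->j", tgt, PROLATE_X, tgt)
    )
    got = out[2, 2, 1, ds.gradients.weighted_indices]
    rel = np.abs(got - analytic) / analytic
    assert rel.mean() < 0.05


def test_per_voxel_rotation_grid_shape_checked(small_phantom):
    with pytest.raises(ValueError):
        angular_resample(
            small_phantom, rotations=np.broadcast_to(np.eye(3), (4, 4, 4, 3, 3))
        )


def test_match_gradient_tables_identity_and_subset(small_phantom):
    out = match_gradient_tables(small_phantom, small_phantom.gradients)
    np.testing.assert_allclose(out.signal, small_phantom.signal, atol=1e-12)

    # subset scheme: every output volume equals the corresponding input volume
    table = small_phantom.gradients
    keep = np.r_[0, table.weighted_indices[:15]]
    sub = GradientTable(table.directions[keep], table.bvalues[keep])
    out2 = match_gradient_tables(small_phantom, sub)
    np.testing.assert_array_equal(
        out2.signal[..., 1:], small_phantom.signal[..., table.weighted_indices[:15]]
    )


def test_match_gradient_tables_rejects_few_directions(small_phantom):
    table = GradientTable(np.eye(3), np.full(3, 1000.0))
    poor = simulate_phantom(
        PhantomSpec(shape=(4, 4, 2), gradient_table=table, n_b0=0)
    )
    with pytest.raises(ValueError):
        match_gradient_tables(poor, small_phantom.gradients)


# --- spherical harmonics


def test_sh_constant_signal_is_pure_degree_zero(small_phantom):
    table = small_phantom.gradients
    sig = small_phantom.signal.copy()
    sig[..., ~table.b0_mask] = 5.0
    ds = small_phantom.copy_with(signal=sig)
    c = sh_fit(ds, order=4, regularization=0.0)
    np.testing.assert_allclose(c[..., 0], 5.0 * np.sqrt(4 * np.pi), atol=1e-9)
    np.testing.assert_allclose(c[..., 1:], 0.0, atol=1e-9)
    # evaluation of degree-0-only coefficients is direction independent
    rng = np.random.default_rng(0)
    d = rng.normal(size=(8, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    vals = sh_eval(c[0, 0, 0], d)
    np.testing.assert_allclose(vals, 5.0, atol=1e-9)


def test_sh_eval_antipodally_symmetric(prolate_phantom64):
    c = sh_fit(prolate_phantom64, order=8)
    rng = np.random.default_rng(1)
    d = rng.normal(size=(16, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    np.testing.assert_allclose(
        sh_eval(c[0, 0, 0], d), sh_eval(c[0, 0, 0], -d), atol=1e-10
    )


def test_sh_fit_reproduces_signal_at_fit_directions(prolate_phantom64):
    ds = prolate_phantom64
    c = sh_fit(ds, order=8)
    vals = sh_eval(c[1, 1, 1], ds.gradients.weighted_directions)
    ref = ds.signal[1, 1, 1, ds.gradients.weighted_indices]
    np.testing.assert_allclose(vals, ref, rtol=5e-3)


def test_sh_rotated_evaluation_matches_analytic(prolate_phantom64):
    ds = prolate_phantom64
    R = rotation_about_z(30.0)
    tgt = ds.gradients.weighted_directions @ R.T
    c = sh_fit(ds, order=8)
    got = sh_eval(c[2, 2, 1], tgt)
    analytic = ds.signal[0, 0, 0, 0] * np.exp(
        -1500.0 * np.einsum("ja,ab,jb->j", tgt, PROLATE_X, tgt)
    )
    rel = np.abs(got - analytic) / analytic
    assert rel.mean() < 0.01


def test_sh_underdetermined_unregularized_raises(small_phantom):
    with pytest.raises(np.linalg.LinAlgError):
        sh_fit(small_phantom, order=8, regularization=0.0)  # 45 coef, 30 dirs


def test_sh_basis_size():
    assert n_sh_coefficients(8) == 45
    d = np.array([[0.0, 0.0, 1.0]])
    assert sh_basis(8, d).shape == (1, 45)
    with pytest.raises(ValueError):
        sh_basis(3, d)


def test_ai_and_sh_backends_agree_on_smooth_signal(prolate_phantom64):
    """Cross-validation of the two intensity-correction backends."""
    ds = prolate_phantom64
    R = rotation_about_z(20.0)
    tgt = ds.gradients.weighted_directions @ R.T
    ai = angular_resample(ds, targets=tgt)[2, 2, 1, ds.gradients.weighted_indices]
    sh = sh_eval(sh_fit(ds, order=8)[2, 2, 1], tgt)
    rel = np.abs(ai - sh) / np.abs(sh)
    assert rel.mean() < 0.06  # each is within its own tolerance of the truth
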