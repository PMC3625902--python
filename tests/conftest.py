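"""Shared phantom fixtures (generated at session scope, all in memory)."""

import numpy as np
import pytest

from dwireg.synthetic import PhantomSpec, simulate_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default two-region phantom: 32x32x16, 30 directions + 3 b0s."""
    return simulate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom():
    """Small two-region phantom for cheap per-operation tests."""
    return simulate_phantom(PhantomSpec(shape=(16, 16, 8)))


@pytest.fixture(scope="session")
def prolate_phantom64():
    """Uniform single-tensor (prolate-x) phantom on a 64-direction scheme.

    The per-voxel signal is spatially constant, so a tiny grid suffices for
    angular-resampling accuracy checks against the closed-form signal.
    """
    return simulate_phantom(
        PhantomSpec(
            shape=(4, 4, 2),
            n_directions=64,
            region_labels=np.full((4, 4, 2), 2),
            s0_texture=False,
        )
    )


@pytest.fixture(scope="session")
def isotropic_smooth_phantom():
    """Isotropic tensor with smooth s0 texture on an 8x8x4 grid.

    On isotropic signal the angular correction is an exact no-op (all
    weighted volumes are equal), which isolates the spatial machinery.
    """
    return simulate_phantom(
        PhantomSpec(
            shape=(8, 8, 4),
            n_directions=6,
            n_b0=1,
            region_labels=np.ones((8, 8, 4), int),
            s0_texture=True,
        )
    )


def rotation_about_z(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
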