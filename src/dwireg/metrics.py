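"""Evaluation statistics: tensor fitting, normalized MSE and fibre
orientation error (foe).

The registration MSE is the mean over voxels and volumes of the squared
intensity difference normalized by the reference maximum intensity, times
100.  The foe is the mean (and sd) of arccos |v_test . v_ref| between the
principal eigenvectors of the fitted diffusion tensors, in degrees; the
absolute value makes it invariant to the eigenvector sign ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import json
import numpy as np

from .io import DWIDataset

__all__ = ["TensorMap", "EvalReport", "fit_tensor", "mse", "foe", "evaluate_pair"]


@dataclass
class TensorMap:
    """Per-voxel diffusion tensors with derived scalars.

    ``tensors``: grid + (3, 3) symmetric matrices (mm^2/s), eigenvalues
    clamped non-negative; ``fa`` in [0, 1]; ``cl`` the Westin linear
    coefficient (lambda1 - lambda2) / (lambda1 + lambda2 + lambda3), which is
    ~0 where the principal direction is degenerate (e.g. balanced fibre
    crossings); ``principal`` the unit first eigenvector (sign-ambiguous);
    ``valid`` flags voxels that were fit.
    """

    tensors: np.ndarray
    fa: np.ndarray
    cl: np.ndarray
    principal: np.ndarray
    valid: np.ndarray
    n_excluded: int = 0


@dataclass
class EvalReport:
    mse: float
    foe_mean: float
    foe_sd: float
    n_mask: int
    mask_description: str = ""
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mse": float(self.mse),
            "foe_mean": float(self.foe_mean),
            "foe_sd": float(self.foe_sd),
            "n_mask": int(self.n_mask),
            "mask_description": self.mask_description,
            "settings": self.settings,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            mse=d["mse"],
            foe_mean=d["foe_mean"],
            foe_sd=d["foe_sd"],
            n_mask=d["n_mask"],
            mask_description=d.get("mask_description", ""),
            settings=d.get("settings", {}),
        )


def fit_tensor(ds: DWIDataset, mask: np.ndarray | None = None) -> TensorMap:
    """Log-linear least-squares tensor fit (unweighted).

    Solves log(S_j / S_0) = -b_j g_j^T D g_j per voxel for the 6 unique
    tensor elements.  Voxels with non-positive signal on any weighted volume
    (or non-positive S0) are excluded and counted.
    """
    table = ds.gradients
    if table.n_weighted < 6:
        raise ValueError("tensor fitting needs at least 6 weighted directions")
    shape = ds.spatial_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    g = table.weighted_directions
    b = table.weighted_bvalues
    # design for [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]
    X = -b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    pinv = np.linalg.pinv(X)

    s0 = ds.s0
    sig = ds.signal[..., table.weighted_indices]
    positive = (s0 > 0) & np.all(sig > 0, axis=-1)
    usable = mask & positive
    n_excluded = int(np.count_nonzero(mask & ~positive))

    tensors = np.zeros(shape + (3, 3))
    fa = np.zeros(shape)
    cl = np.zeros(shape)
    principal = np.zeros(shape + (3,))
    if np.any(usable):
        y = np.log(sig[usable] / s0[usable, None])
        d6 = y @ pinv.T
        D = np.zeros(d6.shape[:-1] + (3, 3))
        D[..., 0, 0], D[..., 1, 1], D[..., 2, 2] = d6[..., 0], d6[..., 1], d6[..., 2]
        D[..., 0, 1] = D[..., 1, 0] = d6[..., 3]
        D[..., 0, 2] = D[..., 2, 0] = d6[..., 4]
        D[..., 1, 2] = D[..., 2, 1] = d6[..., 5]
        evals, evecs = np.linalg.eigh(D)
        evals = np.maximum(evals, 0.0)  # clamp
        md = evals.mean(axis=-1)
        num = np.sum((evals - md[..., None]) ** 2, axis=-1)
        den = np.sum(evals**2, axis=-1)
        fa_v = np.sqrt(1.5 * np.divide(num, den, out=np.zeros_like(num), where=den > 0))
        tensors[usable] = D
        fa[usable] = np.clip(fa_v, 0.0, 1.0)
        tr = evals.sum(axis=-1)
        cl[usable] = np.divide(
            evals[..., 2] - evals[..., 1], tr, out=np.zeros_like(tr), where=tr > 0
        )
        principal[usable] = evecs[..., :, 2]  # largest eigenvalue last in eigh
    return TensorMap(tensors, fa, cl, principal, usable, n_excluded)


def mse(ref: DWIDataset, test: DWIDataset, mask: np.ndarray | None = None) -> float:
    """Mean squared intensity difference normalized by ref I_max, x 100."""
    if ref.spatial_shape != test.spatial_shape or ref.gradients.m != test.gradients.m:
        raise ValueError("datasets must share grid and gradient table")
    if mask is None:
        mask = np.ones(ref.spatial_shape, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    diff = (test.signal[mask] - ref.signal[mask]) / ref.i_max
    return float(np.mean(diff**2) * 100.0)


def foe(
    ref_vecs: np.ndarray, test_vecs: np.ndarray, mask: np.ndarray | None = None
):
    """Mean and sd (degrees) of arccos |v_test . v_ref| over the mask."""
    ref_vecs = np.asarray(ref_vecs, dtype=float)
    test_vecs = np.asarray(test_vecs, dtype=float)
    if mask is None:
        mask = np.ones(ref_vecs.shape[:-1], dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    a = ref_vecs[mask]
    bv = test_vecs[mask]
    dots = np.abs(np.sum(a * bv, axis=-1))
    ang = np.degrees(np.arccos(np.clip(dots, 0.0, 1.0)))
    return float(ang.mean()), float(ang.std())


def evaluate_pair(
    ref: DWIDataset,
    registered: DWIDataset,
    mask_spec: str = "fa:0.2",
    mask: np.ndarray | None = None,
) -> EvalReport:
    """MSE and foe between a reference and a registered dataset.

    The default foe mask keeps anisotropic tissue with a well-defined
    orientation: FA(ref) above the ``fa:<thr>`` threshold, inside the
    reference s0 support (a stand-in for white-matter ROI masks, which
    require external atlas data), and Westin linear coefficient above 0.1 —
    where the first and second eigenvalues tie (balanced crossings) the
    principal direction is degenerate and its angle carries no information.
    An explicit boolean ``mask`` overrides ``mask_spec``.
    """
    tm_ref = fit_tensor(ref)
    tm_reg = fit_tensor(registered)
    if mask is None:
        if not mask_spec.startswith("fa:"):
            raise ValueError(f"unsupported mask spec {mask_spec!r}")
        thr = float(mask_spec.split(":", 1)[1])
        brain = ref.s0 > 0.05 * ref.s0.max()
        mask = (
            brain & (tm_ref.fa > thr) & (tm_ref.cl > 0.1)
            & tm_ref.valid & tm_reg.valid
        )
        desc = f"FA(ref) > {thr} and CL(ref) > 0.1 within s0 support"
    else:
        mask = mask & tm_ref.valid & tm_reg.valid
        desc = "user-supplied"
    m, sd = foe(tm_ref.principal, tm_reg.principal, mask)
    return EvalReport(
        mse=mse(ref, registered, mask),
        foe_mean=m,
        foe_sd=sd,
        n_mask=int(mask.sum()),
        mask_description=desc,
        settings={"mask_spec": mask_spec},
    )
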