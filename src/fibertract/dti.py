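"""Diffusion tensor estimation and scalar maps.

Tensor fitting is the classical log-linear least-squares estimator: per voxel,
log S = log S0 - b g^T D g is solved over a design matrix with the 6 unique
tensor elements plus an intercept.  Eigenvalues are sorted descending and
negative values are clamped to zero (flagged per voxel).  Scalar maps follow
the standard definitions

    AD = l1,  RD = (l2 + l3) / 2,  MD = (l1 + l2 + l3) / 3,
    FA = sqrt(3/2) * sqrt(sum (li - MD)^2) / sqrt(sum li^2)

with FA of an all-zero tensor defined as 0.

The module also provides a simplified kernel-weighted average of
ball-and-sticks fields for building population-average multi-tensor volumes:
compartments are matched greedily across inputs by angular deviation (under
antipodal symmetry), each matched group's orientation is the principal
eigenvector of the weight-and-fraction-weighted sum of dyads v v^T, and
groups supported by too few inputs are dropped.  This is deliberately a
simplified mixture-averaging rule, not a full data-adaptive kernel
regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import DiffusionScheme
from .volumes import MultiTensorVolume, ScalarMaps, TensorVolume

__all__ = [
    "fit_dti_loglinear",
    "tensor_eigensystem",
    "compute_scalar_maps",
    "average_multitensor_kernel",
    "Eigensystem",
]

_SIGNAL_FLOOR = 1e-10


def _design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """Rows: [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    b = scheme.bvalues
    g = scheme.directions
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti_loglinear(
    dwi: np.ndarray,
    scheme: DiffusionScheme,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
    wls: bool = False,
) -> TensorVolume:
    """Log-linear least-squares tensor fit.

    Parameters
    ----------
    dwi : (X, Y, Z, V) signal volume matching ``scheme``.
    mask : optional boolean volume; voxels outside are left zero.
    wls : run a second weighted pass with weights S_hat^2 (the standard WLS
        refinement of the log-linear estimator).

    Signals at or below zero are clamped to a small positive floor before the
    log.  Voxels whose signal is entirely zero are flagged ``degenerate`` and
    given a zero tensor.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != scheme.n_volumes:
        raise ValueError("dwi volume count does not match scheme")
    if dwi.shape[-1] < 7:
        raise ValueError("need >= 7 volumes (6 tensor elements + intercept)")
    if affine is None:
        affine = np.eye(4)
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    A = _design_matrix(scheme)
    if np.linalg.matrix_rank(A) < 7:
        raise ValueError("rank-deficient design: gradient directions collinear")
    vox = dwi[mask]  # (n, V)
    degenerate_rows = np.all(vox <= 0, axis=1)
    logs = np.log(np.clip(vox, _SIGNAL_FLOOR, None))
    coef, *_ = np.linalg.lstsq(A, logs.T, rcond=None)  # (7, n)
    if wls:
        # weights = predicted squared signal, per the usual WLS refinement
        w = np.exp(A @ coef) ** 2  # (V, n)
        for i in range(coef.shape[1]):
            Aw = A * w[:, i : i + 1]
            coef[:, i] = np.linalg.solve(A.T @ Aw, Aw.T @ logs[i])
    coef[:, degenerate_rows] = 0.0
    tensors = np.zeros(shape + (6,))
    s0 = np.zeros(shape)
    # design order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) matches TensorVolume layout
    tensors[mask] = coef[1:].T
    s0[mask] = np.exp(coef[0])
    s0[mask] = np.where(degenerate_rows, 0.0, s0[mask])
    degenerate = np.zeros(shape, dtype=bool)
    degenerate[mask] = degenerate_rows
    return TensorVolume(tensors=tensors, mask=mask, affine=affine, s0=s0,
                        degenerate=degenerate)


@dataclass
class Eigensystem:
    """Descending eigenvalues and eigenvectors of a tensor field."""

    eigenvalues: np.ndarray  # (..., 3) descending, clamped >= 0
    eigenvectors: np.ndarray  # (..., 3, 3), [..., :, i] is the i-th vector
    clamped: np.ndarray  # (...,) bool, True where negatives were clamped
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None


def tensor_eigensystem(tensor: TensorVolume | np.ndarray) -> Eigensystem:
    """Eigen-decomposition with descending eigenvalues.

    Negative eigenvalues are clamped to zero and flagged.  The principal
    eigenvector's sign is normalized so its first non-zero component among
    (x, y, z) is positive.
    """
    if isinstance(tensor, TensorVolume):
        mats = tensor.full_matrices()
        mask, affine = tensor.mask, tensor.affine
    else:
        mats = np.asarray(tensor, dtype=float)
        if mats.shape[-1] == 6:
            mats = TensorVolume(mats, np.ones(mats.shape[:-1], bool), np.eye(4)).full_matrices()
        mask = affine = None
    if not np.all(np.isfinite(mats)):
        raise ValueError("non-finite tensor input")
    vals, vecs = np.linalg.eigh(mats)  # ascending
    vals = vals[..., ::-1]
    vecs = vecs[..., ::-1]
    clamped = np.any(vals < 0, axis=-1)
    vals = np.clip(vals, 0.0, None)
    # sign convention: first non-zero of (x, y, z) positive, for e1 and the rest
    for i in range(3):
        v = vecs[..., :, i]
        sign = np.where(
            np.abs(v[..., 0]) > 1e-12,
            np.sign(v[..., 0]),
            np.where(np.abs(v[..., 1]) > 1e-12, np.sign(v[..., 1]), np.sign(v[..., 2])),
        )
        sign = np.where(sign == 0, 1.0, sign)
        vecs[..., :, i] = v * sign[..., None]
    return Eigensystem(vals, vecs, clamped, mask=mask, affine=affine)


def compute_scalar_maps(eig: Eigensystem) -> ScalarMaps:
    """FA / MD / RD / AD from clamped eigenvalues."""
    l1, l2, l3 = (eig.eigenvalues[..., i] for i in range(3))
    md = (l1 + l2 + l3) / 3.0
    ad = l1
    rd = (l2 + l3) / 2.0
    num = (l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(num) / np.sqrt(den)
    fa = np.where(den > 0, fa, 0.0)
    mask = eig.mask if eig.mask is not None else np.ones(md.shape, dtype=bool)
    affine = eig.affine if eig.affine is not None else np.eye(4)
    return ScalarMaps(fa=fa, md=md, rd=rd, ad=ad, mask=mask, affine=affine,
                      clamped=eig.clamped)


def _principal_dyadic(vectors: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Principal eigenvector of sum_i w_i v_i v_i^T (antipodally symmetric)."""
    dyad = np.einsum("i,ij,ik->jk", weights, vectors, vectors)
    vals, vecs = np.linalg.eigh(dyad)
    v = vecs[:, -1]
    # deterministic sign: first non-zero component positive
    for c in v:
        if abs(c) > 1e-12:
            return v if c > 0 else -v
    return v


def average_multitensor_kernel(
    fields: list[MultiTensorVolume],
    weights: np.ndarray | None = None,
    min_support: float = 0.5,
    match_angle_deg: float = 30.0,
) -> MultiTensorVolume:
    """Kernel-weighted average of ball-and-sticks fields on a common grid.

    Per voxel, compartments from all inputs are matched greedily by smallest
    angular deviation (antipodally symmetric, threshold ``match_angle_deg``).
    Each group's orientation is the principal eigenvector of the
    weight-and-fraction-weighted dyadic sum; its fraction is the weighted mean
    of the member fractions.  Groups supported by fewer than
    ``min_support * n_fields`` inputs are dropped.  Isotropic fraction and
    diffusivities are weighted means.
    """
    if not fields:
        raise ValueError("need at least one field")
    ref = fields[0]
    for f in fields[1:]:
        if not ref.same_grid(f):
            raise ValueError("fields are not on a common grid")
    n = len(fields)
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    K = ref.max_compartments
    shape = ref.grid_shape
    cos_thr = np.cos(np.radians(match_angle_deg))

    out_frac = np.zeros(shape + (K,))
    out_ori = np.zeros(shape + (K, 3))
    out_sd = np.zeros(shape + (K,))
    iso_f = np.zeros(shape)
    iso_d = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)

    stack_frac = np.stack([f.fractions for f in fields])  # (n, X, Y, Z, K)
    any_stick = (stack_frac > 0).any(axis=(0, 4))
    iso_f = np.einsum("n,nxyz->xyz", weights, np.stack([f.iso_fraction for f in fields]))
    iso_d = np.einsum("n,nxyz->xyz", weights, np.stack([f.iso_diffusivity for f in fields]))
    mask = np.stack([f.mask for f in fields]).any(axis=0)

    for i, j, k in np.argwhere(any_stick):
        # gather (field index, fraction, orientation, diffusivity)
        members: list[tuple[int, float, np.ndarray, float]] = []
        for fi, f in enumerate(fields):
            for c in range(f.max_compartments):
                fr = f.fractions[i, j, k, c]
                if fr > 0:
                    members.append(
                        (fi, fr, f.orientations[i, j, k, c],
                         f.stick_diffusivities[i, j, k, c])
                    )
        # greedy grouping: seed groups in descending weighted-fraction order
        members.sort(key=lambda m: -weights[m[0]] * m[1])
        groups: list[list[tuple[int, float, np.ndarray, float]]] = []
        axes: list[np.ndarray] = []
        for m in members:
            best, best_cos = -1, cos_thr
            for gi, ax in enumerate(axes):
                c = abs(float(np.dot(ax, m[2])))
                if c >= best_cos and all(g[0] != m[0] for g in groups[gi]):
                    best, best_cos = gi, c
            if best < 0:
                groups.append([m])
                axes.append(m[2] / np.linalg.norm(m[2]))
            else:
                groups[best].append(m)
                w = np.array([weights[g[0]] * g[1] for g in groups[best]])
                axes[best] = _principal_dyadic(
                    np.array([g[2] for g in groups[best]]), w
                )
        # keep groups with enough support, largest mean fraction first
        kept = []
        for gi, g in enumerate(groups):
            if len({m[0] for m in g}) >= min_support * n - 1e-9:
                wsum = sum(weights[m[0]] for m in g)
                frac = sum(weights[m[0]] * m[1] for m in g) / weights.sum()
                sd = sum(weights[m[0]] * m[3] for m in g) / wsum
                kept.append((frac, axes[gi], sd))
        kept.sort(key=lambda t: -t[0])
        for c, (frac, ax, sd) in enumerate(kept[:K]):
            out_frac[i, j, k, c] = frac
            out_ori[i, j, k, c] = ax
            out_sd[i, j, k, c] = sd

    total = out_frac.sum(axis=-1) + iso_f
    over = total > 1.0
    if over.any():  # numeric guard after dropping/merging groups
        scale = np.where(over, (1.0 - iso_f) / np.maximum(out_frac.sum(axis=-1), 1e-12), 1.0)
        out_frac *= scale[..., None]
    return MultiTensorVolume(
        fractions=out_frac,
        orientations=out_ori,
        stick_diffusivities=out_sd,
        iso_fraction=iso_f,
        iso_diffusivity=iso_d,
        mask=mask,
        affine=ref.affine,
    )
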