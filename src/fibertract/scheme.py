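"""Diffusion gradient schemes.

A :class:`DiffusionScheme` bundles the b-values and unit gradient directions of
a DWI acquisition.  The default scheme mirrors a preclinical Bruker protocol:
42 non-collinear directions at b = 2,800 s/mm^2 plus 4 b0 volumes.  Directions
are spread by electrostatic repulsion on the sphere from a fixed seed so the
default scheme is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DiffusionScheme",
    "default_scheme",
    "repulsion_directions",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]

_UNIT_TOL = 1e-8


@dataclass(frozen=True)
class DiffusionScheme:
    """b-values (s/mm^2) and unit gradient directions of a DWI protocol.

    b0 volumes carry b = 0 and a zero direction vector.  All non-zero
    directions must be unit norm to within 1e-8.
    """

    bvalues: np.ndarray
    directions: np.ndarray
    n_b0: int = field(init=False)

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvalues, dtype=float)
        dirs = np.asarray(self.directions, dtype=float)
        if bvals.ndim != 1 or dirs.shape != (bvals.size, 3):
            raise ValueError("bvalues must be (n,) and directions (n, 3)")
        if bvals.size and bvals.min() < 0:
            raise ValueError("negative b-value")
        dwi = bvals > 0
        norms = np.linalg.norm(dirs[dwi], axis=1)
        if dwi.any() and np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("non-unit gradient direction")
        n_b0 = int(np.sum(~dwi))
        if n_b0 < 1:
            raise ValueError("scheme needs at least one b0 volume")
        object.__setattr__(self, "bvalues", bvals)
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "n_b0", n_b0)

    @property
    def n_volumes(self) -> int:
        return int(self.bvalues.size)

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvalues > 0


def repulsion_directions(n: int, seed: int = 20240, n_iter: int = 2000) -> np.ndarray:
    """Spread ``n`` unit vectors by electrostatic repulsion with antipodal
    symmetry, starting from a seeded uniform draw.  Deterministic."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.01
    for _ in range(n_iter):
        # antipodally symmetric Coulomb forces: each pair interacts through
        # both v_j and -v_j; distances clamped so coincident points separate
        # without numerically exploding
        diff_p = v[:, None, :] - v[None, :, :]
        diff_m = v[:, None, :] + v[None, :, :]
        dp = np.maximum(np.linalg.norm(diff_p, axis=-1), 0.05)
        dm = np.maximum(np.linalg.norm(diff_m, axis=-1), 0.05)
        np.fill_diagonal(dp, np.inf)
        np.fill_diagonal(dm, np.inf)
        force = (diff_p / dp[..., None] ** 3).sum(axis=1) + (
            diff_m / dm[..., None] ** 3
        ).sum(axis=1)
        # project onto the tangent plane, cap the step, and renormalize
        force -= (force * v).sum(axis=1, keepdims=True) * v
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        force = force / np.maximum(norm, 1.0)
        v += step * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        step *= 0.999
    return v


def default_scheme(
    n_directions: int = 42, bvalue: float = 2800.0, n_b0: int = 4, seed: int = 20240
) -> DiffusionScheme:
    """42-direction, b = 2,800 s/mm^2 scheme with 4 leading b0 volumes."""
    dirs = repulsion_directions(n_directions, seed=seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    return DiffusionScheme(bvals, directions)


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> DiffusionScheme:
    """Read an FSL-style bvals/bvecs pair (bvecs: one row per axis)."""
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DiffusionScheme(bvals, bvecs)


def write_bvals_bvecs(
    scheme: DiffusionScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    np.savetxt(bval_path, scheme.bvalues[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")
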