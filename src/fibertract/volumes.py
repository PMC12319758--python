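"""Volumetric containers: diffusion tensors, DTI scalar maps, and
ball-and-sticks (multi-tensor) fields on a regular grid.

All containers share the NIfTI convention of a 4x4 voxel-to-world affine in
millimetres.  Multi-tensor fields hold up to ``K`` anisotropic "stick"
compartments per voxel (volume fraction, unit orientation, parallel
diffusivity) plus an isotropic "ball" for the remaining signal fraction.
Orientations are antipodally symmetric: ``v`` and ``-v`` denote the same
fiber population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["TensorVolume", "ScalarMaps", "MultiTensorVolume", "save_nifti", "load_nifti"]


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine)


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor in mm^2/s.

    ``tensors`` stores the 6 unique elements in the order
    (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) on the last axis.
    """

    tensors: np.ndarray  # (X, Y, Z, 6)
    mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray  # (4, 4)
    s0: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # all-zero-signal voxels

    def full_matrices(self) -> np.ndarray:
        """Expand to (X, Y, Z, 3, 3) symmetric matrices."""
        t = self.tensors
        out = np.zeros(t.shape[:-1] + (3, 3), dtype=t.dtype)
        out[..., 0, 0] = t[..., 0]
        out[..., 1, 1] = t[..., 1]
        out[..., 2, 2] = t[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = t[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = t[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = t[..., 5]
        return out


@dataclass
class ScalarMaps:
    """DTI scalar maps: FA (unitless), MD/RD/AD (mm^2/s), on a shared grid."""

    fa: np.ndarray
    md: np.ndarray
    rd: np.ndarray
    ad: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    clamped: np.ndarray | None = None  # voxels with negative eigenvalues clamped

    METRICS = ("FA", "MD", "RD", "AD")

    def get(self, metric: str) -> np.ndarray:
        return {"FA": self.fa, "MD": self.md, "RD": self.rd, "AD": self.ad}[
            metric.upper()
        ]

    def save(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        for m in self.METRICS:
            save_nifti(self.get(m), self.affine, f"{prefix}_{m}.nii.gz")


@dataclass
class MultiTensorVolume:
    """Ball-and-sticks field: up to K sticks plus an isotropic ball per voxel.

    Unused compartment slots carry fraction 0.  Invariant: the stick fractions
    plus the ball fraction sum to at most 1 (up to 1e-6) in every voxel.
    """

    fractions: np.ndarray  # (X, Y, Z, K)
    orientations: np.ndarray  # (X, Y, Z, K, 3), unit where fraction > 0
    stick_diffusivities: np.ndarray  # (X, Y, Z, K) mm^2/s (parallel)
    iso_fraction: np.ndarray  # (X, Y, Z)
    iso_diffusivity: np.ndarray  # (X, Y, Z) mm^2/s
    mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        total = self.fractions.sum(axis=-1) + self.iso_fraction
        if np.any(total > 1.0 + 1e-6):
            raise ValueError("compartment fractions sum above 1")
        live = self.fractions > 0
        norms = np.linalg.norm(self.orientations, axis=-1)
        if np.any(np.abs(norms[live] - 1.0) > 1e-6):
            raise ValueError("non-unit stick orientation")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[:3]

    @property
    def max_compartments(self) -> int:
        return self.fractions.shape[3]

    def same_grid(self, other: "MultiTensorVolume") -> bool:
        return self.grid_shape == other.grid_shape and np.allclose(
            self.affine, other.affine
        )

    def save(self, prefix: str | Path) -> None:
        """Write a 4D NIfTI stack plus a JSON sidecar naming the layout."""
        prefix = str(prefix)
        K = self.max_compartments
        planes = [self.fractions[..., k] for k in range(K)]
        for k in range(K):
            for ax in range(3):
                planes.append(self.orientations[..., k, ax])
        for k in range(K):
            planes.append(self.stick_diffusivities[..., k])
        planes += [self.iso_fraction, self.iso_diffusivity, self.mask.astype(float)]
        save_nifti(np.stack(planes, axis=-1), self.affine, prefix + ".nii.gz")
        layout = {
            "n_compartments": K,
            "order": ["fractions", "orientations", "stick_diffusivities",
                      "iso_fraction", "iso_diffusivity", "mask"],
        }
        Path(prefix + ".json").write_text(json.dumps(layout, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "MultiTensorVolume":
        prefix = str(prefix)
        stack, affine = load_nifti(prefix + ".nii.gz")
        K = json.loads(Path(prefix + ".json").read_text())["n_compartments"]
        fr = np.stack([stack[..., k] for k in range(K)], axis=-1)
        ori = np.zeros(stack.shape[:3] + (K, 3))
        for k in range(K):
            for ax in range(3):
                ori[..., k, ax] = stack[..., K + 3 * k + ax]
        sd = np.stack([stack[..., 4 * K + k] for k in range(K)], axis=-1)
        return cls(
            fractions=fr,
            orientations=ori,
            stick_diffusivities=sd,
            iso_fraction=stack[..., 5 * K],
            iso_diffusivity=stack[..., 5 * K + 1],
            mask=stack[..., 5 * K + 2] > 0.5,
            affine=affine,
        )
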