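"""Multi-bundle phantom construction and ball-and-sticks DWI simulation.

A phantom is a small 3D grid populated by tubular fiber bundles.  Each bundle
is a smooth centerline (natural cubic spline through control points) swept by
a tube of fixed radius; voxels inside the tube receive a stick compartment
oriented along the local centerline tangent.  Where tubes overlap (crossing
regions) a voxel holds one stick per bundle.  The remaining signal fraction is
an isotropic ball.  The forward signal model is the standard ball-and-sticks
equation

    S(g, b) = S0 * [ f_iso * exp(-b d_iso) + sum_k f_k * exp(-b lam_par (g.v_k)^2) ]

with optional Rician noise (magnitude of a complex Gaussian perturbation with
sigma = S0 / SNR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .scheme import DiffusionScheme
from .volumes import MultiTensorVolume

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "BundleGeometry",
    "make_bundle_geometry",
    "rasterize_multitensor_phantom",
    "simulate_dwi",
    "default_phantom_spec",
]


@dataclass(frozen=True)
class BundleSpec:
    """One tubular bundle: centerline control points (world mm), tube radius
    (mm), stick diffusivities (mm^2/s) and the intra-tube stick fraction."""

    name: str
    control_points: np.ndarray  # (n, 3) world mm
    radius: float  # mm
    lambda_par: float = 1.7e-3
    lambda_perp: float = 0.3e-3
    fraction: float = 0.7

    def __post_init__(self) -> None:
        cp = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        object.__setattr__(self, "control_points", cp)
        if cp.shape[0] < 2:
            raise ValueError(f"bundle {self.name!r}: centerline needs >= 2 points")
        if self.radius <= 0:
            raise ValueError(f"bundle {self.name!r}: radius must be positive")
        if not (self.lambda_par >= self.lambda_perp > 0):
            raise ValueError(f"bundle {self.name!r}: need lambda_par >= lambda_perp > 0")
        if not (0 < self.fraction <= 1):
            raise ValueError(f"bundle {self.name!r}: fraction must lie in (0, 1]")


@dataclass(frozen=True)
class PhantomSpec:
    """Grid geometry plus bundle definitions and background diffusivity."""

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    voxel_size: float = 0.25  # mm isotropic
    bundles: tuple[BundleSpec, ...] = ()
    background_diffusivity: float = 0.7e-3  # mm^2/s, isotropic ball
    max_compartments: int = 3

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def voxel_centers(self) -> np.ndarray:
        """World-mm coordinates of all voxel centers, shape (X, Y, Z, 3)."""
        nx, ny, nz = self.grid_shape
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        return np.stack([ii, jj, kk], axis=-1) * self.voxel_size


@dataclass
class BundleGeometry:
    """Arc-length parameterized centerline with its tube voxel mask."""

    name: str
    curve: CubicSpline  # maps arc length (mm) -> world point
    length: float  # total arc length, mm
    tube_mask: np.ndarray  # (X, Y, Z) bool
    tangents: np.ndarray  # (X, Y, Z, 3) unit tangent at nearest curve point

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        t = self.curve(np.clip(s, 0.0, self.length), 1)
        return t / np.linalg.norm(t, axis=-1, keepdims=True)


def _arclength_spline(points: np.ndarray) -> tuple[CubicSpline, float]:
    """Natural cubic spline through the control points, re-parameterized by
    arc length (chord-length initial parameter, refined by dense resampling)."""
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))]
    if chord[-1] == 0:
        raise ValueError("degenerate centerline: coincident control points")
    # not-a-knot ends track curved centerlines (e.g. arcs) much better than
    # natural ends; fall back for the short point counts it cannot handle
    bc = "not-a-knot" if len(points) >= 4 else "natural"
    base = CubicSpline(chord, points, bc_type=bc)
    # measure arc length on a dense sampling, then re-fit against it
    tt = np.linspace(0.0, chord[-1], max(200, 20 * len(points)))
    pts = base(tt)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.r_[0.0, np.cumsum(seg)]
    length = float(s[-1])
    keep = np.r_[True, np.diff(s) > 1e-12]
    return CubicSpline(s[keep], pts[keep], bc_type="not-a-knot"), length


def make_bundle_geometry(spec: PhantomSpec) -> dict[str, BundleGeometry]:
    """Build, per bundle, the arc-length spline, the tube voxel mask (voxel
    centers within ``radius`` of the curve) and the tangent field.

    Raises if a centerline leaves the grid or is degenerate.
    """
    centers = spec.voxel_centers()
    flat = centers.reshape(-1, 3)
    lo = -0.5 * spec.voxel_size
    hi = (np.array(spec.grid_shape) - 0.5) * spec.voxel_size
    out: dict[str, BundleGeometry] = {}
    for b in spec.bundles:
        curve, length = _arclength_spline(b.control_points)
        samples = curve(np.linspace(0, length, max(64, int(length / (0.25 * spec.voxel_size)))))
        if np.any(samples < lo) or np.any(samples > hi):
            raise ValueError(f"bundle {b.name!r}: centerline leaves the grid")
        # distance from each voxel center to the sampled polyline
        d2 = np.full(flat.shape[0], np.inf)
        nearest = np.zeros(flat.shape[0], dtype=int)
        for i, p in enumerate(samples):
            di = np.einsum("ij,ij->i", flat - p, flat - p)
            closer = di < d2
            d2[closer] = di[closer]
            nearest[closer] = i
        inside = d2 <= b.radius**2
        s_grid = np.linspace(0, length, len(samples))
        tang = np.zeros_like(flat)
        tang[inside] = curve(s_grid[nearest[inside]], 1)
        nrm = np.linalg.norm(tang[inside], axis=1, keepdims=True)
        tang[inside] = tang[inside] / nrm
        out[b.name] = BundleGeometry(
            name=b.name,
            curve=curve,
            length=length,
            tube_mask=inside.reshape(spec.grid_shape),
            tangents=tang.reshape(spec.grid_shape + (3,)),
        )
    return out


def rasterize_multitensor_phantom(
    spec: PhantomSpec,
) -> tuple[MultiTensorVolume, dict[str, BundleGeometry]]:
    """Populate the grid: one stick per overlapping bundle (renormalized if
    their fractions sum above 1) plus an isotropic ball for the remainder;
    pure ball outside all tubes."""
    geoms = make_bundle_geometry(spec)
    K = spec.max_compartments
    shape = spec.grid_shape
    frac = np.zeros(shape + (K,))
    ori = np.zeros(shape + (K, 3))
    sdiff = np.zeros(shape + (K,))
    count = np.zeros(shape, dtype=int)
    for b in spec.bundles:
        g = geoms[b.name]
        idx = np.argwhere(g.tube_mask)
        for i, j, k in idx:
            c = count[i, j, k]
            if c >= K:
                raise ValueError(
                    f"more than {K} bundles overlap voxel {(i, j, k)} "
                    f"(adding {b.name!r})"
                )
            frac[i, j, k, c] = b.fraction
            ori[i, j, k, c] = g.tangents[i, j, k]
            sdiff[i, j, k, c] = b.lambda_par
            count[i, j, k] = c + 1
    total = frac.sum(axis=-1)
    over = total > 1.0
    if over.any():
        frac[over] /= total[over][..., None]
        total = frac.sum(axis=-1)
    iso_frac = 1.0 - total
    iso_d = np.full(shape, spec.background_diffusivity)
    vol = MultiTensorVolume(
        fractions=frac,
        orientations=ori,
        stick_diffusivities=sdiff,
        iso_fraction=iso_frac,
        iso_diffusivity=iso_d,
        mask=np.ones(shape, dtype=bool),
        affine=spec.affine,
    )
    return vol, geoms


def simulate_dwi(
    field: MultiTensorVolume,
    scheme: DiffusionScheme,
    s0: float = 1000.0,
    snr: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Ball-and-sticks forward signal, optionally with Rician noise.

    Noise is the magnitude of a complex Gaussian perturbation with
    sigma = s0 / snr, the standard magnitude-MRI noise model.  ``snr=None``
    (or infinite) returns the noiseless signal exactly.
    """
    if snr is not None and not np.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive")
    b = scheme.bvalues  # (V,)
    g = scheme.directions  # (V, 3)
    # iso: (X,Y,Z,V)
    signal = field.iso_fraction[..., None] * np.exp(
        -field.iso_diffusivity[..., None] * b
    )
    dots = np.einsum("xyzkc,vc->xyzkv", field.orientations, g)  # (X,Y,Z,K,V)
    att = np.exp(-b * field.stick_diffusivities[..., None] * dots**2)
    signal += np.einsum("xyzk,xyzkv->xyzv", field.fractions, att)
    signal *= s0
    if snr is None or np.isinf(snr):
        return signal
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    real = signal + rng.normal(0.0, sigma, signal.shape)
    imag = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(real**2 + imag**2)


@dataclass
class PhantomGroundTruth:
    """What the phantom actually contains, for validating reconstruction."""

    bundle_masks: dict  # name -> (X, Y, Z) bool
    orientations: dict  # name -> (X, Y, Z, 3) unit tangents on the mask
    core_scalar_means: dict  # name -> {FA, MD, RD, AD} of the pure in-tube mix
    injured_bundles: tuple = ()

    def __post_init__(self) -> None:
        for b in self.injured_bundles:
            if b not in self.bundle_masks:
                raise ValueError(f"injured bundle {b!r} not in the atlas")
        for b, means in self.core_scalar_means.items():
            if not all(np.isfinite(v) for v in means.values()):
                raise ValueError(f"non-finite true scalar means for {b!r}")


def phantom_ground_truth(
    spec: PhantomSpec,
    geoms: dict[str, BundleGeometry],
    scheme: DiffusionScheme,
    injured: tuple = (),
) -> PhantomGroundTruth:
    """True per-bundle masks, tangent fields and core scalar means.

    Core means are the DTI scalars of the pure in-tube composition (one
    stick at the bundle fraction plus the background ball), obtained by
    fitting the noiseless forward signal of a single such voxel — the value
    an ideal measurement deep inside the tube would return.
    """
    from .dti import compute_scalar_maps, fit_dti_loglinear, tensor_eigensystem

    core_means = {}
    for b in spec.bundles:
        field = MultiTensorVolume(
            fractions=np.array([[[[b.fraction] + [0.0] * (spec.max_compartments - 1)]]]),
            orientations=np.broadcast_to(
                np.array([1.0, 0.0, 0.0]), (1, 1, 1, spec.max_compartments, 3)
            ).copy(),
            stick_diffusivities=np.full((1, 1, 1, spec.max_compartments), b.lambda_par),
            iso_fraction=np.array([[[1.0 - b.fraction]]]),
            iso_diffusivity=np.array([[[spec.background_diffusivity]]]),
            mask=np.ones((1, 1, 1), dtype=bool),
            affine=np.eye(4),
        )
        sig = simulate_dwi(field, scheme, s0=1.0)
        maps = compute_scalar_maps(
            tensor_eigensystem(fit_dti_loglinear(sig, scheme))
        )
        core_means[b.name] = {
            m: float(maps.get(m)[0, 0, 0]) for m in ("FA", "MD", "RD", "AD")
        }
    return PhantomGroundTruth(
        bundle_masks={n: g.tube_mask for n, g in geoms.items()},
        orientations={n: g.tangents for n, g in geoms.items()},
        core_scalar_means=core_means,
        injured_bundles=tuple(injured),
    )


def prototype_streamlines(
    geom: BundleGeometry,
    radius: float,
    n_lines: int = 9,
    step: float = 0.2,
    offset_scale: float = 0.5,
) -> list[np.ndarray]:
    """Deterministic prototype streamlines for a bundle: the centerline plus
    parallel copies offset on perpendicular spokes at ``offset_scale *
    radius``.  Used to build TOMs for phantom bundles, standing in for the
    manually delineated prototypes of a real pipeline."""
    s = np.arange(0.0, geom.length + 1e-9, step)
    if s[-1] < geom.length:
        s = np.append(s, geom.length)
    center = geom.curve(s)
    tang = geom.tangent_at(s)
    # stable normal frame: pick the axis least aligned with the mean tangent
    ref = np.eye(3)[np.argmin(np.abs(geom.tangent_at(geom.length / 2)))]
    n1 = np.cross(tang, ref)
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tang, n1)
    lines = [center]
    for a in np.linspace(0, 2 * np.pi, n_lines - 1, endpoint=False):
        off = offset_scale * radius * (np.cos(a) * n1 + np.sin(a) * n2)
        lines.append(center + off)
    return lines


def default_phantom_spec(
    grid_shape: tuple[int, int, int] = (48, 48, 24),
    voxel_size: float = 0.25,
    stick_fraction: float = 0.7,
) -> PhantomSpec:
    """Desk-scale phantom with a straight tube, a 90-degree crossing pair and
    an arc, loosely evoking left/right homologous rodent bundles."""
    nx, ny, nz = grid_shape
    vs = voxel_size
    xmax, ymax = (nx - 1) * vs, (ny - 1) * vs
    zmid = (nz // 2) * vs
    r = 2.0 * vs

    def line(p0, p1):
        return np.array([p0, np.mean([p0, p1], axis=0), p1])

    y_l, y_r = 0.70 * ymax, 0.30 * ymax
    bundles = (
        # straight left bundle along x
        BundleSpec("fimbria_L", line((0.06 * xmax, y_l, zmid), (0.94 * xmax, y_l, zmid)),
                   radius=r, fraction=stick_fraction),
        BundleSpec("fimbria_R", line((0.06 * xmax, y_r, zmid), (0.94 * xmax, y_r, zmid)),
                   radius=r, fraction=stick_fraction),
        # 90-degree crossing pair at the grid center
        BundleSpec("intcap_L",
                   line((0.10 * xmax, 0.5 * ymax, zmid), (0.90 * xmax, 0.5 * ymax, zmid)),
                   radius=r, fraction=0.5),
        BundleSpec("thalsub_L",
                   line((0.5 * xmax, 0.10 * ymax, zmid), (0.5 * xmax, 0.90 * ymax, zmid)),
                   radius=r, fraction=0.5),
    )
    return PhantomSpec(grid_shape=grid_shape, voxel_size=vs, bundles=bundles)
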