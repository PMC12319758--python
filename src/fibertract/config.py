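"""Structured-config (YAML/JSON) loading and saving for phantom and cohort
specifications, so simulation studies are reproducible from plain-text files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .cohort import CohortSpec
from .phantom import BundleSpec, PhantomSpec

__all__ = ["load_phantom_spec", "save_phantom_spec",
           "load_cohort_spec", "save_cohort_spec"]


def _read(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _write(payload: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=1))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    d = _read(path)
    bundles = tuple(
        BundleSpec(
            name=b["name"],
            control_points=np.asarray(b["control_points"], dtype=float),
            radius=float(b["radius"]),
            lambda_par=float(b.get("lambda_par", 1.7e-3)),
            lambda_perp=float(b.get("lambda_perp", 0.3e-3)),
            fraction=float(b.get("fraction", 0.7)),
        )
        for b in d.get("bundles", [])
    )
    return PhantomSpec(
        grid_shape=tuple(d.get("grid_shape", (48, 48, 24))),
        voxel_size=float(d.get("voxel_size", 0.25)),
        bundles=bundles,
        background_diffusivity=float(d.get("background_diffusivity", 0.7e-3)),
        max_compartments=int(d.get("max_compartments", 3)),
    )


def save_phantom_spec(spec: PhantomSpec, path: str | Path) -> None:
    payload = {
        "grid_shape": list(spec.grid_shape),
        "voxel_size": spec.voxel_size,
        "background_diffusivity": spec.background_diffusivity,
        "max_compartments": spec.max_compartments,
        "bundles": [
            {
                "name": b.name,
                "control_points": np.asarray(b.control_points).tolist(),
                "radius": b.radius,
                "lambda_par": b.lambda_par,
                "lambda_perp": b.lambda_perp,
                "fraction": b.fraction,
            }
            for b in spec.bundles
        ],
    }
    _write(payload, path)


def load_cohort_spec(path: str | Path) -> CohortSpec:
    d = _read(path)
    kwargs = {}
    for key in (
        "site_factors", "injured_effects", "timepoint",
        "apnea_log_median", "apnea_log_sd", "sham_apnea_log_median",
        "sham_apnea_log_sd", "apnea_coupling", "sham_missing_rate",
        "tbi_missing_rate", "subject_sd_scale", "atlas_seed",
    ):
        if key in d:
            kwargs[key] = d[key]
    if "site_counts" in d:
        kwargs["site_counts"] = {s: tuple(c) for s, c in d["site_counts"].items()}
    if "bundles" in d:
        kwargs["bundles"] = tuple(d["bundles"])
    return CohortSpec(**kwargs)


def save_cohort_spec(spec: CohortSpec, path: str | Path) -> None:
    payload = {
        "site_counts": {s: list(c) for s, c in spec.site_counts.items()},
        "site_factors": dict(spec.site_factors),
        "bundles": list(spec.bundles),
        "injured_effects": {b: dict(e) for b, e in spec.injured_effects.items()},
        "timepoint": spec.timepoint,
        "apnea_log_median": float(spec.apnea_log_median),
        "apnea_log_sd": spec.apnea_log_sd,
        "apnea_coupling": spec.apnea_coupling,
        "sham_missing_rate": spec.sham_missing_rate,
        "tbi_missing_rate": spec.tbi_missing_rate,
        "atlas_seed": spec.atlas_seed,
    }
    _write(payload, path)
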