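"""Bundle-specific tractography: TOM priors, compartment-selecting
deterministic tracking, and per-bundle scalar summaries.

The tract orientation map (TOM) built from prototype streamlines steers the
tracker through the 90-degree crossing: at each step the stick compartment
closest in angle to the running direction is followed, so the bundle is
reconstructed straight through the intersection instead of switching tracts.
"""

import numpy as np

import fibertract as ft
from fibertract.phantom import prototype_streamlines
from fibertract.tracking import StreamlineSet

spec = ft.default_phantom_spec()
scheme = ft.default_scheme()
volume, geoms = ft.rasterize_multitensor_phantom(spec)
dwi = ft.simulate_dwi(volume, scheme)
maps = ft.compute_scalar_maps(
    ft.tensor_eigensystem(ft.fit_dti_loglinear(dwi, scheme, affine=spec.affine))
)

params = ft.TrackingParams(max_length=15.0)
for name in ("fimbria_L", "intcap_L"):
    g = geoms[name]
    proto = StreamlineSet(prototype_streamlines(g, 2.0 * spec.voxel_size), name)
    tom = ft.compute_tom(proto, spec.grid_shape, spec.affine)
    lines = ft.track_bundle(volume, tom, params)
    summary = ft.summarize_bundle(lines, maps, min_count=params.min_count)
    lens = [(l.shape[0] - 1) * params.step_size for l in lines.streamlines]
    print(f"{name}: {len(lines)} streamlines from {lines.n_seeds} seeds, "
          f"median length {np.median(lens):.1f} mm (tube {g.length:.1f} mm)")
    print(f"  bundle means: " + "  ".join(
        f"{m} {summary.means[m]:.4g}" for m in ("FA", "MD", "RD", "AD")))

print("\nintcap_L passes through the thalsub_L crossing; its streamlines run")
print("the full tube because compartment selection follows the TOM prior.")
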