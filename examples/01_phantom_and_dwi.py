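"""Build a crossing-fiber phantom and simulate its diffusion-weighted signal.

The phantom is a 48x48x24 grid at 0.25 mm with two straight "fimbria" tubes
and a 90-degree crossing pair; the signal model is ball-and-sticks at
b = 2,800 s/mm^2 over 42 directions plus 4 b0 volumes.
"""

import numpy as np

import fibertract as ft

spec = ft.default_phantom_spec()
scheme = ft.default_scheme()
volume, geoms = ft.rasterize_multitensor_phantom(spec)

print("bundles and tube sizes (voxels):")
for name, g in geoms.items():
    print(f"  {name:12s} length {g.length:5.2f} mm, {int(g.tube_mask.sum())} voxels")

dwi = ft.simulate_dwi(volume, scheme, s0=1000.0, snr=30, seed=0)
print(f"\nDWI volume: {dwi.shape}, b0 mean {dwi[..., 0].mean():.1f}")

# attenuation inside a tube vs the isotropic background
inside = geoms["fimbria_L"].tube_mask
bg = ~np.any([g.tube_mask for g in geoms.values()], axis=0)
dwi_mean_in = dwi[inside][:, scheme.dwi_mask].mean()
dwi_mean_bg = dwi[bg][:, scheme.dwi_mask].mean()
print(f"mean DWI signal inside fimbria_L: {dwi_mean_in:.1f}")
print(f"mean DWI signal in background:    {dwi_mean_bg:.1f}")
print("(anisotropic tubes retain more signal along perpendicular gradients,")
print(" the isotropic background attenuates equally in every direction)")
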