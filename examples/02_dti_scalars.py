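"""Fit diffusion tensors to simulated DWI and derive FA / MD / RD / AD maps.

The log-linear least-squares estimator recovers the tensor exactly on
noiseless data; with Rician noise at a realistic SNR the maps acquire the
usual small bias, quantified here.
"""

import numpy as np

import fibertract as ft

spec = ft.default_phantom_spec()
scheme = ft.default_scheme()
volume, geoms = ft.rasterize_multitensor_phantom(spec)

clean = ft.simulate_dwi(volume, scheme)
noisy = ft.simulate_dwi(volume, scheme, snr=30, seed=1)

for label, dwi in (("noiseless", clean), ("SNR 30", noisy)):
    tensors = ft.fit_dti_loglinear(dwi, scheme, affine=spec.affine)
    maps = ft.compute_scalar_maps(ft.tensor_eigensystem(tensors))
    core = geoms["fimbria_L"].tube_mask
    print(f"{label:10s} fimbria_L core: FA {maps.fa[core].mean():.3f}  "
          f"MD {maps.md[core].mean():.2e} mm^2/s  "
          f"AD {maps.ad[core].mean():.2e}  RD {maps.rd[core].mean():.2e}")

print("\nFA near 0.7-0.8 inside the tube (one stick + ball), near 0 in the")
print("isotropic background; MD sits near the mixture-weighted diffusivity.")
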