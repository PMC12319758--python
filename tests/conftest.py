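import numpy as np
import pytest

import fibertract as ft
from fibertract.phantom import prototype_streamlines
from fibertract.tracking import StreamlineSet, compute_tom


@pytest.fixture(scope="session")
def scheme():
    return ft.default_scheme()


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale phantom with a straight tube pair and a 90-degree crossing."""
    spec = ft.default_phantom_spec()
    vol, geoms = ft.rasterize_multitensor_phantom(spec)
    return spec, vol, geoms


@pytest.fixture(scope="session")
def straight_tom(small_phantom):
    spec, vol, geoms = small_phantom
    g = geoms["fimbria_L"]
    proto = StreamlineSet(
        prototype_streamlines(g, 2.0 * spec.voxel_size), "fimbria_L"
    )
    return compute_tom(proto, spec.grid_shape, spec.affine)


@pytest.fixture(scope="session")
def scalar_maps(small_phantom, scheme):
    spec, vol, _ = small_phantom
    dwi = ft.simulate_dwi(vol, scheme)
    tv = ft.fit_dti_loglinear(dwi, scheme, affine=spec.affine)
    return ft.compute_scalar_maps(ft.tensor_eigensystem(tv))
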