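import numpy as np
import pytest

import ichwm


@pytest.fixture(scope="session")
def scheme():
    return ichwm.default_scheme()


@pytest.fixture(scope="session")
def small_layout():
    return ichwm.PhantomLayout.small()


@pytest.fixture(scope="session")
def small_grid(small_layout):
    return ichwm.Grid(small_layout.grid_shape, small_layout.voxel_spacing)


@pytest.fixture(scope="session")
def small_phantom(small_layout):
    """Noise-free small phantom with a 3 mL hematoma and a disrupted shell."""
    spec = ichwm.phantom_spec(small_layout, hematoma_volume_ml=3.0, noise_sigma=0.0)
    field, gt = ichwm.generate_tensor_field(spec)
    return spec, field, gt


@pytest.fixture(scope="session")
def small_noiseless_dwi(small_phantom, scheme):
    spec, field, gt = small_phantom
    return ichwm.simulate_dwi(field, scheme, ichwm.s0_map(spec, gt), 0.0)


@pytest.fixture(scope="session")
def symmetric_fa_map(small_layout):
    """Lesion-free phantom FA map: perfectly left-right symmetric by construction."""
    spec = ichwm.phantom_spec(small_layout, hematoma_volume_ml=None, noise_sigma=0.0)
    _, gt = ichwm.generate_tensor_field(spec)
    return ichwm.ScalarMap(gt.true_fa_map, "FA", small_layout.voxel_spacing)
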