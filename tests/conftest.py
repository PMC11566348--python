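import numpy as np
import pytest

from hiprelax import Contrast, RelaxationMap, make_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """Compact annular atlas used across tests (4 slices, 64x64 in-plane)."""
    return make_atlas(
        grid_shape=(4, 64, 64),
        head_center=(32.0, 32.0),
        femur_radii=(11.0, 13.0),
        acetab_radii=(15.0, 17.0),
    )


@pytest.fixture
def t1rho_times():
    return np.array([0.0, 15.0, 30.0, 45.0])


def constant_map(atlas, value, contrast=Contrast.T1RHO):
    """Map with one constant value on the atlas cartilage, invalid elsewhere."""
    mask = atlas.femur_mask | atlas.acetab_mask
    values = np.where(mask, float(value), np.nan)
    return RelaxationMap(values, np.where(mask, 100.0, np.nan), mask.copy(), contrast)
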