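import numpy as np
import pytest
from hypothesis import settings

import bcoms

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_embryo():
    """Compact noiseless multi-cell embryo with exact geometry."""
    spec = bcoms.SyntheticEmbryoSpec(
        shape=(3, 16, 40, 40), semi_axes=(6.5, 17.0, 18.0), n_cells=4,
        noise_sd=0.0, gap_fraction=0.0, depth_attenuation=1.0, bleach_rate=1.0,
        rng_seed=11,
    )
    return spec, *bcoms.generate_embryo(spec)


@pytest.fixture(scope="session")
def degraded_embryo():
    """Small embryo with all degradations switched on."""
    spec = bcoms.SyntheticEmbryoSpec(
        shape=(3, 16, 40, 40), semi_axes=(6.5, 17.0, 18.0), n_cells=4, rng_seed=11
    )
    return spec, *bcoms.generate_embryo(spec)


@pytest.fixture(scope="session")
def single_cell_embryo():
    spec = bcoms.SyntheticEmbryoSpec(
        shape=(3, 20, 48, 48), semi_axes=(8.0, 20.0, 21.0), n_cells=1,
        noise_sd=0.0, gap_fraction=0.0, rng_seed=5,
    )
    return spec, *bcoms.generate_embryo(spec)


def brute_force_mask_mean(values: np.ndarray, mask: np.ndarray) -> float:
    """Voxel-loop oracle for masked-mean objectives."""
    num = 0.0
    den = 0
    flat_v = values.ravel()
    flat_m = mask.ravel()
    for i in range(flat_v.size):
        if flat_m[i]:
            num += flat_v[i]
            den += 1
    return num / den
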