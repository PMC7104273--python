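import numpy as np
import pytest

from dectexture import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


def small_config(**overrides):
    """Phantom config scaled down for fast tests: tiny grid, three energies."""
    defaults = dict(
        image_shape=(3, 40, 40),
        voxel_size_mm=(3.0, 0.7, 0.7),
        energies_keV=(40.0, 60.0, 80.0),
        sweep_energies_keV=(40.0, 60.0, 80.0),
        n_benign=3,
        n_malignant=3,
        nodule_axes_mm=(5.5, 8.0),
        rng_seed=11,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(small_config())


@pytest.fixture()
def disk_mask():
    """Single-slice circular mask (radius 8 voxels) inside a 3-slice volume."""
    shape = (3, 24, 24)
    zz, yy, xx = np.indices(shape)
    return ((zz == 1) & ((yy - 12) ** 2 + (xx - 12) ** 2 <= 64))
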