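import numpy as np
import pytest

from wmischemia import defaults as dflt
from wmischemia.phantom import AcquisitionScheme, PhantomSpec, default_spec


@pytest.fixture(scope="session")
def scheme():
    return AcquisitionScheme()


@pytest.fixture(scope="session")
def small_spec():
    """A light cohort spec on a 16x16x4 grid for fast end-to-end tests."""
    return default_spec(grid_shape=(16, 16, 4), n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def noiseless_spec():
    """No Rician / Gaussian noise and no within-region truth jitter, so the
    pipeline should recover the planted maps to numerical precision."""
    return default_spec(grid_shape=(16, 16, 4), n_subjects=2, seed=5,
                        snr_dwi=np.inf, dsc_noise_sd=0.0,
                        voxel_sd=dict(fa=0.0, md=0.0, tmax=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
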