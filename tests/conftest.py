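import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from plimox import (
    AcquisitionModel,
    ParameterMaps,
    RegularizerSpec,
    RetinaPhantomSpec,
    generate_po2_map,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionModel:
    """Default acquisition: 10 equally spaced phases, Pd-porphyrin constants."""
    return AcquisitionModel.default()


@pytest.fixture(scope="session")
def reg_spec() -> RegularizerSpec:
    """Preset regularizer: l=0.5, p=0.1, q=0.025, beta=5, 13x13 window."""
    return RegularizerSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """100x100 retina phantom used across estimation tests."""
    spec = RetinaPhantomSpec(n_rows=100, n_cols=100, seed=7)
    return generate_po2_map(spec)


def smooth_field(shape, rng, mean=1.0, scale=0.2, sigma=3.0):
    """Smooth strictly positive random field (bounded away from zero)."""
    f = gaussian_filter(rng.normal(mean, scale, shape), sigma)
    return f + mean


def random_params(shape, rng, baseline=2.0) -> ParameterMaps:
    """Random parameter maps with positive a1, b1 (valid phase quadrant)."""
    a1 = rng.uniform(0.2, 0.8, shape)
    b1 = rng.uniform(0.2, 0.8, shape)
    a0 = np.full(shape, baseline)
    return ParameterMaps(a0=a0, a1=a1, b1=b1)
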