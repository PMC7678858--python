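import warnings

import numpy as np
import pytest

from lfholo.optics import FresnelSamplingWarning, OpticsConfig

# The coarse test grids legitimately undersample the Fresnel chirp; the
# warning itself is exercised explicitly in test_optics.
warnings.simplefilter("ignore", FresnelSamplingWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def optics():
    return OpticsConfig()


@pytest.fixture(scope="session")
def benchmark_unwrapper():
    """Reduced network trained once per session under the scaled-down
    benchmark conditions (sparse super-λ/2 scenes, a few CPU minutes)."""
    from lfholo.benchmark import train_benchmark_unwrapper
    return train_benchmark_unwrapper(seed=2024)
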