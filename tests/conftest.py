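import numpy as np
import pytest

import tdcperf as tp


@pytest.fixture(scope="session")
def default_spec():
    return tp.PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Default noisy phantom (SNR 20, lesion delay 10 s, 3T long-TR protocol)."""
    return tp.generate_phantom(default_spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    return tp.generate_phantom(tp.PhantomSpec(snr=np.inf))


@pytest.fixture(scope="session")
def full_pipeline(phantom):
    """All four parameter maps on the default phantom (shared: computing the
    Tmax branch once keeps the suite fast)."""
    series, truth = phantom
    return tp.compute_parameter_maps(series, truth.brain_mask, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast phantom for CLI / IO round trips."""
    return tp.PhantomSpec(
        grid_shape=(24, 24, 4),
        lesion_center=(8, 12, 2),
        lesion_radius=1.5,
        slice_delays=(0.0, 0.7, 1.4, 2.1),
    )
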