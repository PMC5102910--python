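import numpy as np
import pytest

from catrace import (DriftParams, FixtureSpec, PipelineConfig, generate_trace,
                     standard_tr_fixture)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def times_2hz():
    """120 s at 2 samples per second."""
    return np.arange(0.0, 120.0, 0.5)


@pytest.fixture(scope="session")
def clean_tr_trace():
    """One noiseless transient on a drifting baseline, with ground truth."""
    spec = standard_tr_fixture(seed=0, snr=20)
    spec.noise_sd = 0.0
    return generate_trace(spec)


@pytest.fixture(scope="session")
def noise_trace_factory():
    def make(seed, sd=0.02):
        spec = FixtureSpec(drift=DriftParams(z=1.0), tr=None, noise_sd=sd, seed=seed)
        return generate_trace(spec)[0]
    return make
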