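import numpy as np
import pytest

from fuzzyfuse import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, bias-free, sharp-boundary phantom (the exact limit)."""
    spec = PhantomSpec(shape=(48, 48), snr_noise=0.0, bias_amplitude=0.0,
                       pv_width=0.0, seed=7)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default study-condition phantom: partial volumes, 20% bias, 5% noise."""
    spec = PhantomSpec(shape=(48, 48), snr_noise=0.05, seed=11)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
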