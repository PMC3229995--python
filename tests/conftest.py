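import numpy as np
import pytest
from hypothesis import settings

from cupwear import PhantomSpec, generate_scan_pair

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noisy_pair():
    """One default phantom pair at the study noise level (sigma 0.1 mm)."""
    spec = PhantomSpec(seed=42, noise_sigma=0.1)
    pre, post, truth = generate_scan_pair(spec)
    return pre, post, truth


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, outlier-free, unrepositioned pair with 0.5 mm x-wear."""
    spec = PhantomSpec(
        seed=7, noise_sigma=0.0, outlier_fraction=0.0,
        wear_vector_true=(0.5, 0.0, 0.0), reposition=False,
    )
    pre, post, truth = generate_scan_pair(spec)
    return pre, post, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
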