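import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cvrkit as ck

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def windows_a():
    return ck.windows_for_design("A")


@pytest.fixture(scope="session")
def windows_b():
    return ck.windows_for_design("B")


@pytest.fixture(scope="session")
def clean_subject_a():
    """Noise-free Design A subject with 2% responses and a 10 mmHg step."""
    return ck.synthesize_subject(design="A", a1_pct=2.0, a2_pct=2.0,
                                 delta_petco2=10.0, noise_sd=0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230615)
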