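import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    from myovowel.bayes_filter import FilterParams

    return FilterParams()


@pytest.fixture
def fitted_bounds():
    from myovowel.formant_map import default_bounds

    return default_bounds()
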