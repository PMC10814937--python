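import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_records():
    from lesioncolor import load_study_fixture

    return load_study_fixture()


@pytest.fixture(scope="session")
def lesion_sample():
    """One default synthetic photograph shared across tests."""
    from lesioncolor.synthetic import SyntheticLesionSpec, generate_lesion_image

    return generate_lesion_image(SyntheticLesionSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
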