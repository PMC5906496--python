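import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tzreact as tz

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_dataset() -> tz.FixtureDataset:
    return tz.load_fixture()


@pytest.fixture(scope="session")
def fixture_model(fixture_dataset) -> tz.ReactivityModel:
    return tz.calibrate(tz.fixture_calibration_points(fixture_dataset))


@pytest.fixture(scope="session")
def printed_barriers() -> dict[str, float]:
    return tz.iedda.printed_activation_energies()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20171129)
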