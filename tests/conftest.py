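from datetime import datetime

import numpy as np
import pytest

from rehabwear import ScenarioConfig, generate_cohort
from rehabwear.pipeline import process_session


@pytest.fixture(scope="session")
def day_config() -> ScenarioConfig:
    """One patient, one 24-h day, default study conditions."""
    return ScenarioConfig(n_patients=1, sessions=("0W",), session_hours=24.0, rng_seed=11)


@pytest.fixture(scope="session")
def day_cohort(day_config):
    return generate_cohort(day_config)


@pytest.fixture(scope="session")
def day_session(day_cohort):
    profile = day_cohort.profiles[0]
    return profile, day_cohort.sessions[(profile.patient_id, "0W")]


@pytest.fixture(scope="session")
def day_processed(day_session):
    profile, data = day_session
    return process_session(data.accel, data.hr, data.schedule, profile, "0W")


@pytest.fixture(scope="session")
def twoday_cohort():
    """Full 48-h session with the device-swap marker, 2 patients."""
    cfg = ScenarioConfig(n_patients=2, sessions=("0W",), session_hours=48.0, rng_seed=4)
    return generate_cohort(cfg)


def const_accel(vec, seconds=60.0, rate=25.0, start=None, gaps=()):
    n = int(seconds * rate)
    t = np.arange(n) / rate
    xyz = np.tile(np.asarray(vec, dtype=float), (n, 1))
    from rehabwear import AccelSeries

    return AccelSeries(
        t=t, xyz=xyz, rate=rate,
        start=start or datetime(2020, 1, 6, 0, 0), gaps=list(gaps),
    )


@pytest.fixture
def make_accel():
    return const_accel
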