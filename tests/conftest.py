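from datetime import date, datetime

import pytest
from hypothesis import HealthCheck, settings

from adhema.types import (
    ActuationEvent,
    EmaReport,
    Medication,
    Regimen,
    Source,
    StudyConfig,
)

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config():
    return StudyConfig()


@pytest.fixture
def regimen():
    return Regimen("P01", date(2015, 8, 1), date(2015, 9, 29), 1, 1)


def event(
    pid="P01",
    ts="2015-08-01T08:00",
    medication=Medication.CONTROLLER,
    source=Source.DEVICE,
):
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts)
    return ActuationEvent(pid, ts, medication, source)


def report(pid="P01", ts="2015-08-01T09:00", **responses):
    if isinstance(ts, str):
        ts = datetime.fromisoformat(ts)
    return EmaReport(pid, ts, responses)


@pytest.fixture
def make_event():
    return event


@pytest.fixture
def make_report():
    return report
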