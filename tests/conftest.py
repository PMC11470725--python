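import pytest
from hypothesis import HealthCheck, settings

from fallstrat import generate_fixture
from fallstrat.cohort_model import FallsCount, PatientRecord, TriState

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 392-record cohort realising the printed path counts."""
    return generate_fixture()


def make_record(**kwargs) -> PatientRecord:
    """A valid baseline record; override whichever fields the test exercises."""
    base = dict(patient_id="p1", age=80, sex="female",
                fall_past_year=TriState.NO,
                falls_count_category=FallsCount.ZERO, cfs=4)
    base.update(kwargs)
    return PatientRecord(**base)
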