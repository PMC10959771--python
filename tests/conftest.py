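import datetime as dt

import pytest

from claimlines import (
    DiagnosisEvent,
    DispensingEvent,
    PatientBundle,
    default_config,
    generate,
    load_code_rules,
)

BASE = dt.date(2018, 1, 1)
CUTOFF = dt.date(2019, 12, 31)


def day(n: int) -> dt.date:
    """Day offset from the 2018-01-01 anchor used by hand-traced fixtures."""
    return BASE + dt.timedelta(days=n)


def make_bundle(
    pid="P1",
    sex="F",
    birth=dt.date(1955, 6, 15),
    death=None,
    last=CUTOFF,
    trial=False,
    disp=(),
    dx=(),
):
    """Build a bundle from (date, drug, supply) and (date, icd10) tuples."""
    return PatientBundle(
        patient_id=pid,
        sex=sex,
        birth_date=birth,
        death_date=death,
        last_record_date=last,
        trial_flag=trial,
        dispensings=tuple(
            DispensingEvent(pid, d, drug, supply) for d, drug, supply in disp
        ),
        diagnoses=tuple(DiagnosisEvent(pid, d, code) for d, code in dx),
    )


def refills(drug, start_day, end_day, step=30, supply=30):
    """(date, drug, supply) refill tuples every `step` days in [start, end]."""
    return [(day(d), drug, supply) for d in range(start_day, end_day + 1, step)]


@pytest.fixture(scope="session")
def rules():
    return load_code_rules()


@pytest.fixture(scope="session")
def small_claims():
    """A 400-patient synthetic claims set shared across integration tests."""
    return generate(default_config(n_patients=400, seed=11))
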