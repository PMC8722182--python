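import datetime as dt

import pytest

from raild import (
    AlgorithmParams,
    ClaimsBundle,
    CodeSystem,
    DiagnosisEvent,
    DrugClass,
    DrugEvent,
    EnrollmentSpan,
    HospitalStay,
    ProcedureEvent,
    ProcedureKind,
    Setting,
    Specialty,
    default_registry,
)

D0 = dt.date(2008, 1, 1)


def day(n: int) -> dt.date:
    """Day ``n`` of the test calendar (day 0 = 2008-01-01)."""
    return D0 + dt.timedelta(days=n)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def params():
    return AlgorithmParams()


def dx(
    pid="p1",
    on=0,
    code="714.0",
    system=CodeSystem.ICD9CM,
    setting=Setting.OUTPATIENT,
    position=1,
    specialty=Specialty.RHEUMATOLOGIST,
):
    return DiagnosisEvent(pid, day(on), code, system, setting, position, specialty)


def drug(pid="p1", on=0, cls=DrugClass.CSDMARD, name="methotrexate"):
    return DrugEvent(pid, day(on), cls, name)


def span(pid="p1", start=-730, end=3650, a=True, b=True, c=False):
    return EnrollmentSpan(pid, day(start), day(end), a, b, c)


def proc(pid="p1", on=0, kind=ProcedureKind.CHEST_CT, setting=Setting.OUTPATIENT):
    return ProcedureEvent(pid, day(on), kind, setting)


def stay(pid="p1", admit=0, discharge=1):
    return HospitalStay(pid, day(admit), day(discharge))


def bundle(
    diagnoses=(),
    procedures=(),
    drugs=(),
    enrollment=(),
    stays=(),
    start=-1460,
    end=3650,
):
    return ClaimsBundle(
        diagnoses=tuple(diagnoses),
        procedures=tuple(procedures),
        drugs=tuple(drugs),
        enrollment=tuple(enrollment),
        stays=tuple(stays),
        data_start=day(start),
        data_end=day(end),
    )
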