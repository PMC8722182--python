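"""Claims event data model.

Administrative claims arrive as flat event tables: diagnoses, procedures,
drug dispensings, enrollment spans, and hospital stays.  Every downstream
algorithm (cohort identification, case finding, incident classification)
scans these typed event streams.  Dates are calendar dates with no time
component; all window arithmetic downstream is in whole days, because
claims carry service dates only.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, replace
from typing import Iterable


class CodeSystem(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"


class Setting(str, enum.Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class Specialty(str, enum.Enum):
    RHEUMATOLOGIST = "rheumatologist"
    PULMONOLOGIST = "pulmonologist"
    INTERNIST = "internist"
    OTHER = "other"
    UNKNOWN = "unknown"


class ProcedureKind(str, enum.Enum):
    CHEST_CT = "chest_ct"
    LUNG_BIOPSY = "lung_biopsy"
    HOME_OXYGEN = "home_oxygen"


class DrugClass(str, enum.Enum):
    CSDMARD = "csDMARD"
    BDMARD = "bDMARD"
    TSDMARD = "tsDMARD"
    GLUCOCORTICOID = "glucocorticoid"
    SMOKING_CESSATION = "smoking_cessation"
    OTHER = "other"


#: Drug classes that satisfy the DMARD-treatment requirement for cohort entry.
DMARD_CLASSES = frozenset({DrugClass.CSDMARD, DrugClass.BDMARD, DrugClass.TSDMARD})


class AdjudicationOutcome(str, enum.Enum):
    CONFIRMED = "confirmed"
    NOT_CONFIRMED = "not_confirmed"
    INSUFFICIENT = "insufficient"
    NOT_RETRIEVABLE = "not_retrievable"


class IncidenceClass(str, enum.Enum):
    INCIDENT = "incident"
    PREVALENT = "prevalent"
    UNCLASSIFIABLE = "unclassifiable"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True, order=True)
class DiagnosisEvent:
    """One diagnosis code on one claim line.

    ``position`` is the ordinal of the diagnosis on the claim (1 = primary);
    it is meaningful only for inpatient claims.  ``specialty`` is the billing
    provider's specialty, pre-resolved to an enum — the algorithms use it
    only as a filter, so no provider table join is modelled.
    """

    patient_id: str
    service_date: dt.date
    code: str
    code_system: CodeSystem
    setting: Setting = Setting.OUTPATIENT
    position: int = 1
    specialty: Specialty = Specialty.UNKNOWN


@dataclass(frozen=True, order=True)
class ProcedureEvent:
    patient_id: str
    service_date: dt.date
    kind: ProcedureKind
    setting: Setting = Setting.OUTPATIENT


@dataclass(frozen=True, order=True)
class DrugEvent:
    patient_id: str
    service_date: dt.date
    drug_class: DrugClass
    drug_name: str = ""


@dataclass(frozen=True, order=True)
class EnrollmentSpan:
    """A contiguous enrollment spell with Part A/B/C flags.

    The cohort rule requires Part A and Part B coverage *without* Part C
    (managed care), because Part C enrollment makes fee-for-service claims
    incomplete.
    """

    patient_id: str
    start_date: dt.date
    end_date: dt.date
    part_a: bool = True
    part_b: bool = True
    part_c: bool = False


@dataclass(frozen=True, order=True)
class HospitalStay:
    patient_id: str
    admit_date: dt.date
    discharge_date: dt.date


@dataclass(frozen=True)
class AdjudicationRecord:
    """Gold-standard chart-review outcome for one algorithm-flagged patient."""

    patient_id: str
    outcome: AdjudicationOutcome
    incidence_class: IncidenceClass = IncidenceClass.NOT_APPLICABLE
    onset_date: dt.date | None = None

    def __post_init__(self) -> None:
        if (
            self.incidence_class is not IncidenceClass.NOT_APPLICABLE
            and self.outcome is not AdjudicationOutcome.CONFIRMED
        ):
            raise ValueError(
                "incidence_class may differ from not_applicable only for "
                f"confirmed outcomes (patient {self.patient_id})"
            )


def _sorted(events: Iterable) -> tuple:
    return tuple(sorted(events))


@dataclass(frozen=True)
class ClaimsBundle:
    """A complete claims extract: all event streams plus the data window.

    Events are stored sorted by (patient_id, date, ...) so that every scan
    downstream is deterministic.  ``data_start``/``data_end`` bound the
    observable window; an event outside it is a validation issue.
    """

    diagnoses: tuple[DiagnosisEvent, ...] = ()
    procedures: tuple[ProcedureEvent, ...] = ()
    drugs: tuple[DrugEvent, ...] = ()
    enrollment: tuple[EnrollmentSpan, ...] = ()
    stays: tuple[HospitalStay, ...] = ()
    data_start: dt.date = dt.date(2006, 1, 1)
    data_end: dt.date = dt.date(2015, 12, 31)

    def __post_init__(self) -> None:
        object.__setattr__(self, "diagnoses", _sorted(self.diagnoses))
        object.__setattr__(self, "procedures", _sorted(self.procedures))
        object.__setattr__(self, "drugs", _sorted(self.drugs))
        object.__setattr__(self, "enrollment", _sorted(self.enrollment))
        object.__setattr__(self, "stays", _sorted(self.stays))

    def patient_ids(self) -> list[str]:
        ids = set()
        for stream in (self.diagnoses, self.procedures, self.drugs, self.enrollment, self.stays):
            for ev in stream:
                ids.add(ev.patient_id)
        return sorted(ids)

    def for_patient(self, patient_id: str) -> "ClaimsBundle":
        """Slice of the bundle containing one patient's events."""
        return ClaimsBundle(
            diagnoses=tuple(e for e in self.diagnoses if e.patient_id == patient_id),
            procedures=tuple(e for e in self.procedures if e.patient_id == patient_id),
            drugs=tuple(e for e in self.drugs if e.patient_id == patient_id),
            enrollment=tuple(e for e in self.enrollment if e.patient_id == patient_id),
            stays=tuple(e for e in self.stays if e.patient_id == patient_id),
            data_start=self.data_start,
            data_end=self.data_end,
        )

    def shifted(self, days: int) -> "ClaimsBundle":
        """Translate every date in the bundle by ``days`` (for invariance checks)."""
        d = dt.timedelta(days=days)
        return ClaimsBundle(
            diagnoses=tuple(replace(e, service_date=e.service_date + d) for e in self.diagnoses),
            procedures=tuple(replace(e, service_date=e.service_date + d) for e in self.procedures),
            drugs=tuple(replace(e, service_date=e.service_date + d) for e in self.drugs),
            enrollment=tuple(
                replace(e, start_date=e.start_date + d, end_date=e.end_date + d)
                for e in self.enrollment
            ),
            stays=tuple(
                replace(e, admit_date=e.admit_date + d, discharge_date=e.discharge_date + d)
                for e in self.stays
            ),
            data_start=self.data_start + d,
            data_end=self.data_end + d,
        )


_ICD9_INITIAL = frozenset("0123456789VE")


def code_system_plausible(code: str, system: CodeSystem) -> bool:
    """Cheap syntactic check that a code matches its declared system.

    ICD-9-CM codes start with a digit, ``V`` or ``E``; ICD-10-CM codes start
    with a letter other than ``U`` followed by a digit.  (``E`` and ``V``
    initial letters exist in both systems, so those are accepted for either.)
    """
    if not code:
        return False
    head = code[0].upper()
    if system is CodeSystem.ICD9CM:
        return head in _ICD9_INITIAL
    if head in ("E", "V"):
        return True
    return head.isalpha() and len(code) >= 2 and code[1].isdigit()


def validate_bundle(bundle: ClaimsBundle) -> list[str]:
    """Report every invariant violation in the bundle.

    Returns human-readable issue strings, each naming the patient and field.
    An empty list means the bundle is internally consistent.
    """
    issues: list[str] = []

    def check_date(pid: str, date: dt.date, what: str) -> None:
        if not (bundle.data_start <= date <= bundle.data_end):
            issues.append(
                f"patient {pid}: {what} {date.isoformat()} outside data window "
                f"[{bundle.data_start.isoformat()}, {bundle.data_end.isoformat()}]"
            )

    for e in bundle.diagnoses:
        check_date(e.patient_id, e.service_date, "diagnosis date")
        if not e.code:
            issues.append(f"patient {e.patient_id}: empty diagnosis code")
        elif not code_system_plausible(e.code, e.code_system):
            issues.append(
                f"patient {e.patient_id}: code {e.code!r} inconsistent with "
                f"system {e.code_system.value}"
            )
        if e.position < 1:
            issues.append(f"patient {e.patient_id}: diagnosis position {e.position} < 1")
    for e in bundle.procedures:
        check_date(e.patient_id, e.service_date, "procedure date")
    for e in bundle.drugs:
        check_date(e.patient_id, e.service_date, "drug date")
    for s in bundle.enrollment:
        if s.end_date < s.start_date:
            issues.append(
                f"patient {s.patient_id}: enrollment span end {s.end_date.isoformat()} "
                f"before start {s.start_date.isoformat()}"
            )
    for s in bundle.stays:
        if s.discharge_date < s.admit_date:
            issues.append(
                f"patient {s.patient_id}: hospital stay discharge "
                f"{s.discharge_date.isoformat()} before admission {s.admit_date.isoformat()}"
            )
        check_date(s.patient_id, s.admit_date, "admission date")
        check_date(s.patient_id, s.discharge_date, "discharge date")
    return issues
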