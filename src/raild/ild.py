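"""ILD case finding and incident classification in an RA cohort.

The case-finding rule admits an ILD diagnosis through one of four
case-qualifying configurations:

* ``HospitalPrimary`` — inpatient claim, diagnosis in the primary position;
* ``HospitalNonPrimary`` — inpatient claim, any non-primary position;
* ``OutpatientCT`` — outpatient diagnosis from a pulmonologist,
  rheumatologist, or internist, preceded within 90 days by an outpatient
  chest CT (or outpatient lung biopsy, which serves the same diagnostic
  role);
* ``OutpatientHospital`` — the same outpatient diagnosis preceded within
  90 days by any hospitalization, a surrogate for an in-hospital CT that
  is not separately billed.

A cohort member's ILD case is the earliest final-algorithm-coded diagnosis
whose qualifying event falls strictly after the RA index date.  The
incident classifier then demands a clean history: no specific ILD code,
sarcoidosis code, or lung biopsy from the start of observable data through
``min(index + 365 days, case date − 183 days)``.  Evidence accruing inside
the final 183 days before the case date never disqualifies — an ILD workup
takes months, and those codes are part of the diagnosis being made, not
proof of pre-existing disease.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, replace
from typing import Sequence

from .codesets import CodeRegistry
from .model import (
    ClaimsBundle,
    CodeSystem,
    DiagnosisEvent,
    HospitalStay,
    ProcedureEvent,
    ProcedureKind,
    Setting,
    Specialty,
)
from .params import AlgorithmParams
from .ra_cohort import CohortMember

QUALIFYING_SPECIALTIES = frozenset(
    {Specialty.PULMONOLOGIST, Specialty.RHEUMATOLOGIST, Specialty.INTERNIST}
)


class CaseCategory(enum.Enum):
    HOSPITAL_PRIMARY = "HospitalPrimary"
    HOSPITAL_NON_PRIMARY = "HospitalNonPrimary"
    OUTPATIENT_CT = "OutpatientCT"
    OUTPATIENT_HOSPITAL = "OutpatientHospital"


#: same-day tie-break order: inpatient over outpatient, primary over
#: non-primary, CT-anchored over hospitalization-anchored
CATEGORY_PRIORITY = {
    CaseCategory.HOSPITAL_PRIMARY: 0,
    CaseCategory.HOSPITAL_NON_PRIMARY: 1,
    CaseCategory.OUTPATIENT_CT: 2,
    CaseCategory.OUTPATIENT_HOSPITAL: 3,
}


class IncidentStatus(enum.Enum):
    INCIDENT = "incident"
    PREVALENT_OR_UNCLEAR = "prevalent_or_unclear"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class CaseQualification:
    category: CaseCategory
    anchor_date: dt.date


@dataclass(frozen=True)
class ScreenHit:
    """A patient's first broad-screen ILD diagnosis (specific ∪ sensitive)."""

    patient_id: str
    service_date: dt.date
    code: str
    code_system: CodeSystem


@dataclass(frozen=True)
class IncidentReport:
    status: IncidentStatus
    clean_window_end: dt.date | None
    disqualifying_events: tuple[str, ...] = ()


@dataclass(frozen=True)
class ILDCase:
    patient_id: str
    case_date: dt.date
    qualifying_code: str
    code_system: CodeSystem
    qualification: CaseQualification
    incident: IncidentStatus
    seropositive_proxy: bool
    incident_report: IncidentReport | None = None


def screen_ild(
    diagnoses: Sequence[DiagnosisEvent], registry: CodeRegistry
) -> dict[str, ScreenHit]:
    """First ILD-class diagnosis per patient under the broad screen.

    Any code in the specific or sensitive set counts; this is the highly
    sensitive case-finding pass whose hits feed per-code PPV screening and
    the sensitivity denominator — it is not the case definition.
    """
    hits: dict[str, ScreenHit] = {}
    for d in sorted(diagnoses, key=lambda e: (e.patient_id, e.service_date, e.code)):
        if d.patient_id in hits:
            continue
        if registry.is_ild_screen(d.code, d.code_system):
            hits[d.patient_id] = ScreenHit(d.patient_id, d.service_date, d.code, d.code_system)
    return hits


def qualify_case(
    dx: DiagnosisEvent,
    procedures: Sequence[ProcedureEvent],
    stays: Sequence[HospitalStay],
    params: AlgorithmParams = AlgorithmParams(),
) -> CaseQualification | None:
    """Case-qualifying configuration for one ILD diagnosis, or ``None``.

    Inpatient diagnoses qualify unconditionally (primary vs non-primary by
    claim position).  Outpatient diagnoses require a qualifying specialty
    and a diagnostic anchor — an outpatient chest CT or lung biopsy, or a
    hospitalization — inside the closed window ``[dx − 90 days, dx]``
    (same-day anchors count).  The hospitalization anchor date is the
    discharge date by default (configurable to the admission date).
    """
    if dx.setting is Setting.INPATIENT:
        category = (
            CaseCategory.HOSPITAL_PRIMARY if dx.position == 1 else CaseCategory.HOSPITAL_NON_PRIMARY
        )
        return CaseQualification(category=category, anchor_date=dx.service_date)

    if dx.specialty not in QUALIFYING_SPECIALTIES:
        return None
    ct_window = dt.timedelta(days=params.ct_anchor_window_days)
    hosp_window = dt.timedelta(days=params.hosp_anchor_window_days)

    ct_anchors = [
        p.service_date
        for p in procedures
        if p.patient_id == dx.patient_id
        and p.setting is Setting.OUTPATIENT
        and p.kind in (ProcedureKind.CHEST_CT, ProcedureKind.LUNG_BIOPSY)
        and dx.service_date - ct_window <= p.service_date <= dx.service_date
    ]
    if ct_anchors:
        return CaseQualification(CaseCategory.OUTPATIENT_CT, max(ct_anchors))

    hosp_anchors = []
    for s in stays:
        if s.patient_id != dx.patient_id:
            continue
        anchor = s.discharge_date if params.hospital_anchor == "discharge" else s.admit_date
        if dx.service_date - hosp_window <= anchor <= dx.service_date:
            hosp_anchors.append(anchor)
    if hosp_anchors:
        return CaseQualification(CaseCategory.OUTPATIENT_HOSPITAL, max(hosp_anchors))
    return None


def _seropositive_proxy(diagnoses: Sequence[DiagnosisEvent], registry: CodeRegistry) -> bool:
    return any(registry.is_seropositive_proxy(d.code, d.code_system) for d in diagnoses)


def detect_ild_case(
    member: CohortMember,
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    params: AlgorithmParams = AlgorithmParams(),
    classify: bool = True,
) -> ILDCase | None:
    """Earliest qualifying final-algorithm ILD diagnosis after the RA index.

    Same-day candidates are broken by category priority (HospitalPrimary >
    HospitalNonPrimary > OutpatientCT > OutpatientHospital), then by code
    for full determinism.  With ``home_oxygen_exclusion`` set, a home-oxygen
    dispensing before the case date (a prevalent-ILD proxy) vetoes the case.
    With ``two_code_variant`` set, outpatient-qualified cases additionally
    need a second outpatient final-algorithm code within 365 days.
    """
    patient = bundle.for_patient(member.patient_id)
    candidates: list[tuple[dt.date, int, str, DiagnosisEvent, CaseQualification]] = []
    for d in patient.diagnoses:
        if d.service_date <= member.ra_index_date:
            continue
        if not registry.is_ild_final(d.code, d.code_system):
            continue
        qual = qualify_case(d, patient.procedures, patient.stays, params)
        if qual is None:
            continue
        candidates.append(
            (d.service_date, CATEGORY_PRIORITY[qual.category], d.code, d, qual)
        )
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:3])

    for case_date, _, _, dx, qual in candidates:
        if params.home_oxygen_exclusion and any(
            p.kind is ProcedureKind.HOME_OXYGEN and p.service_date < case_date
            for p in patient.procedures
        ):
            return None
        case = ILDCase(
            patient_id=member.patient_id,
            case_date=case_date,
            qualifying_code=dx.code,
            code_system=dx.code_system,
            qualification=qual,
            incident=IncidentStatus.PREVALENT_OR_UNCLEAR,
            seropositive_proxy=_seropositive_proxy(patient.diagnoses, registry),
        )
        if params.two_code_variant and qual.category in (
            CaseCategory.OUTPATIENT_CT,
            CaseCategory.OUTPATIENT_HOSPITAL,
        ):
            if not two_code_variant(case, patient.diagnoses, registry, params):
                continue  # this candidate fails the stricter variant
        if classify:
            report = classify_incident(case, member, bundle, registry, params)
            case = replace(case, incident=report.status, incident_report=report)
        return case
    return None


def two_code_variant(
    case: ILDCase,
    diagnoses: Sequence[DiagnosisEvent],
    registry: CodeRegistry,
    params: AlgorithmParams = AlgorithmParams(),
) -> bool:
    """Does a second outpatient final-algorithm code follow within the window?

    Only defined for outpatient-qualified cases; the window is the closed
    interval ``(case_date, case_date + 365 days]``.
    """
    if case.qualification.category not in (
        CaseCategory.OUTPATIENT_CT,
        CaseCategory.OUTPATIENT_HOSPITAL,
    ):
        raise ValueError("two-code variant applies only to outpatient-qualified cases")
    limit = case.case_date + dt.timedelta(days=params.two_code_window_days)
    return any(
        d.setting is Setting.OUTPATIENT
        and registry.is_ild_final(d.code, d.code_system)
        and case.case_date < d.service_date <= limit
        for d in diagnoses
        if d.patient_id == case.patient_id
    )


def clean_window_end(
    member: CohortMember, case_date: dt.date, params: AlgorithmParams = AlgorithmParams()
) -> dt.date:
    """Upper bound of the prevalent-disease clean window.

    ``min(index + incident_post_index_clean_days, case − incident_accrual_days)``:
    at least a year past the index must be scanned for prevalent evidence,
    but the final 183 days before the case date are reserved for diagnostic
    accrual and never disqualify.
    """
    return min(
        member.ra_index_date + dt.timedelta(days=params.incident_post_index_clean_days),
        case_date - dt.timedelta(days=params.incident_accrual_days),
    )


def classify_incident(
    case: ILDCase,
    member: CohortMember,
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    params: AlgorithmParams = AlgorithmParams(),
) -> IncidentReport:
    """Classify a detected case as incident or prevalent/unclear.

    Incident requires (a) at least 12 months of observable data before the
    index date, and (b) no specific-ILD or sarcoidosis diagnosis and no
    lung-biopsy procedure anywhere in ``[data_start, clean_window_end]``.
    Sensitive (broad-screen) codes in the baseline do not disqualify.  A
    short pre-index baseline yields ``UNCLASSIFIABLE`` rather than a silent
    drop, so callers can report it distinctly.
    """
    baseline_days = (member.ra_index_date - bundle.data_start).days
    if baseline_days < _min_baseline_days(params):
        return IncidentReport(
            status=IncidentStatus.UNCLASSIFIABLE,
            clean_window_end=None,
            disqualifying_events=(
                f"only {baseline_days} days of pre-index data "
                f"(need {_min_baseline_days(params)})",
            ),
        )
    end = clean_window_end(member, case.case_date, params)
    patient = bundle.for_patient(case.patient_id)
    disqualifiers: list[str] = []
    for d in patient.diagnoses:
        if d.service_date <= end and registry.is_incident_disqualifier(d.code, d.code_system):
            disqualifiers.append(
                f"diagnosis {d.code} ({d.code_system.value}) on {d.service_date.isoformat()}"
            )
    for p in patient.procedures:
        if p.kind is ProcedureKind.LUNG_BIOPSY and p.service_date <= end:
            disqualifiers.append(f"lung biopsy on {p.service_date.isoformat()}")
    status = IncidentStatus.PREVALENT_OR_UNCLEAR if disqualifiers else IncidentStatus.INCIDENT
    return IncidentReport(
        status=status, clean_window_end=end, disqualifying_events=tuple(disqualifiers)
    )


def _min_baseline_days(params: AlgorithmParams) -> int:
    return params.baseline_coverage_months * 365 // 12


def detect_cohort_cases(
    members: Sequence[CohortMember],
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    params: AlgorithmParams = AlgorithmParams(),
) -> list[ILDCase]:
    """Run case finding + incident classification over a whole cohort."""
    cases = []
    for member in sorted(members, key=lambda m: m.patient_id):
        case = detect_ild_case(member, bundle, registry, params)
        if case is not None:
            cases.append(case)
    return cases
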