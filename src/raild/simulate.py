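"""Synthetic Medicare-like claims streams with planted ground truth.

The generator builds patient-level event timelines that satisfy (or
deliberately violate, by exactly one rule) the RA cohort and ILD
case-finding definitions, and records per-patient truth labels so that
every algorithm stage can be checked against a known answer:

* planted RA patients carry a qualifying diagnosis pair, a rheumatologist
  claim, a DMARD dispensing, and a continuous A+B (no C) enrollment span,
  so their true index date is known by construction;
* planted incident ILD patients have a clean baseline, optional diagnostic
  accrual codes inside the 183-day pre-case window, and the anchor events
  (CT, hospitalization, inpatient claim position) their planted
  case-qualifying category requires;
* planted prevalent ILD patients carry early specific-ILD evidence that the
  clean-window scan must find;
* mimics carry sarcoidosis or bronchiectasis-style noise;
* near-miss patients fail exactly one rule by one boundary unit (a 6-day
  diagnosis pair, a CT at 91 days, no rheumatologist claim, a one-day
  coverage gap, a Part C enrollment spell, baseline sarcoidosis).

Events dated before 2015-10-01 use ICD-9-CM codes and later events use
ICD-10-CM codes, mirroring the US coding transition, so both code systems
are exercised.  A single seeded pseudorandom stream drives everything:
identical scenario + seed gives byte-identical bundles.  Event dates are
drawn uniformly within feasibility constraints — reproducibility is valued
over billing realism.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ild import CaseCategory
from .model import (
    AdjudicationOutcome,
    AdjudicationRecord,
    ClaimsBundle,
    CodeSystem,
    DiagnosisEvent,
    DrugClass,
    DrugEvent,
    EnrollmentSpan,
    HospitalStay,
    IncidenceClass,
    ProcedureEvent,
    ProcedureKind,
    Setting,
    Specialty,
)

ICD10_SWITCH = dt.date(2015, 10, 1)

_FINAL_ILD_9 = ["515", "516.31", "516.34", "516.8", "714.81"]
_FINAL_ILD_10 = ["J84.10", "J84.112", "J84.9"]
_SENSITIVE_9 = ["518.89", "494.0", "793.19", "491.9"]
_SENSITIVE_10 = ["R91.8", "J98.4", "J47.9"]
_RA_9 = ["714.0", "714.2"]
_RA_10 = ["M05.79", "M05.9"]
_SARCOID_9 = "135"
_SARCOID_10 = "D86.9"
_DMARDS = [
    ("methotrexate", DrugClass.CSDMARD),
    ("hydroxychloroquine", DrugClass.CSDMARD),
    ("leflunomide", DrugClass.CSDMARD),
    ("etanercept", DrugClass.BDMARD),
    ("adalimumab", DrugClass.BDMARD),
    ("abatacept", DrugClass.BDMARD),
    ("tofacitinib", DrugClass.TSDMARD),
]


class ILDStatus(enum.Enum):
    NONE = "none"
    INCIDENT = "incident"
    PREVALENT = "prevalent"
    MIMIC = "mimic"


class NearMiss(enum.Enum):
    RA_PAIR_6_DAYS = "ra_pair_6_days"
    CT_91_DAYS = "ct_91_days"
    NO_RHEUMATOLOGIST = "no_rheumatologist"
    COVERAGE_GAP = "coverage_gap"
    PART_C_SPELL = "part_c_spell"
    BASELINE_SARCOIDOSIS = "baseline_sarcoidosis"


@dataclass(frozen=True)
class SimulationScenario:
    """Study conditions for one simulated claims extract.

    ``ild_incidence_rate`` is events per 1000 person-years of post-index
    follow-up (default 4.1, the upper end of reported clinically
    significant RA-ILD incidence).  ``fraction_prevalent_ild`` and
    ``fraction_mimics`` are proportions of RA patients.  ``near_miss_rates``
    are proportions of all patients assigned to each single-rule-violation
    variant.
    """

    n_patients: int = 500
    fraction_ra: float = 0.8
    ild_incidence_rate: float = 4.1
    fraction_prevalent_ild: float = 0.05
    fraction_mimics: float = 0.05
    near_miss_rates: Mapping[str, float] = field(default_factory=dict)
    date_range: tuple[dt.date, dt.date] = (dt.date(2006, 1, 1), dt.date(2015, 12, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, value in [
            ("fraction_ra", self.fraction_ra),
            ("fraction_prevalent_ild", self.fraction_prevalent_ild),
            ("fraction_mimics", self.fraction_mimics),
            *self.near_miss_rates.items(),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {value}")
        start, end = self.date_range
        # need baseline year + qualification year + post-index follow-up
        if (end - start).days < 4 * 365:
            raise ValueError("date_range must span at least 4 years for feasible timelines")
        for key in self.near_miss_rates:
            NearMiss(key)  # raises on unknown variant


@dataclass(frozen=True)
class TruthLabel:
    patient_id: str
    is_ra: bool
    ra_true_index: dt.date | None = None
    ild_status: ILDStatus = ILDStatus.NONE
    ild_true_onset: dt.date | None = None
    planted_category: CaseCategory | None = None
    near_miss: NearMiss | None = None


class _Timeline:
    """Accumulates one patient's events during construction."""

    def __init__(self, pid: str):
        self.pid = pid
        self.diagnoses: list[DiagnosisEvent] = []
        self.procedures: list[ProcedureEvent] = []
        self.drugs: list[DrugEvent] = []
        self.enrollment: list[EnrollmentSpan] = []
        self.stays: list[HospitalStay] = []


def _pick(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(len(items)))]


def _ra_code(date: dt.date, rng: np.random.Generator) -> tuple[str, CodeSystem]:
    if date < ICD10_SWITCH:
        return _pick(rng, _RA_9), CodeSystem.ICD9CM
    return _pick(rng, _RA_10), CodeSystem.ICD10CM


def _ild_code(date: dt.date, rng: np.random.Generator) -> tuple[str, CodeSystem]:
    if date < ICD10_SWITCH:
        return _pick(rng, _FINAL_ILD_9), CodeSystem.ICD9CM
    return _pick(rng, _FINAL_ILD_10), CodeSystem.ICD10CM


def _sensitive_code(date: dt.date, rng: np.random.Generator) -> tuple[str, CodeSystem]:
    if date < ICD10_SWITCH:
        return _pick(rng, _SENSITIVE_9), CodeSystem.ICD9CM
    return _pick(rng, _SENSITIVE_10), CodeSystem.ICD10CM


def _sarcoid_code(date: dt.date) -> tuple[str, CodeSystem]:
    if date < ICD10_SWITCH:
        return _SARCOID_9, CodeSystem.ICD9CM
    return _SARCOID_10, CodeSystem.ICD10CM


def _days(rng: np.random.Generator, lo: int, hi: int) -> dt.timedelta:
    """Uniform whole-day offset on the closed interval [lo, hi]."""
    return dt.timedelta(days=int(rng.integers(lo, hi + 1)))


def _plant_ra_qualification(
    tl: _Timeline,
    rng: np.random.Generator,
    start: dt.date,
    end: dt.date,
    index_latest: dt.date,
    rheumatologist: bool = True,
) -> dt.date:
    """Plant enrollment + diagnosis pair + DMARD so the true index = second dx date.

    The enrollment span opens a full coverage year before the first
    diagnosis and runs to the data end, the DMARD lands between the two
    diagnoses, and (by default) the first diagnosis is a rheumatologist
    claim — so the second diagnosis date is the day all three requirements
    are met (no later than ``index_latest``).
    """
    total = (index_latest - start).days
    if total < 372:
        raise ValueError("index_latest leaves no room for a coverage year plus a 7-day pair")
    span_start = start + _days(rng, 0, min(365, total - 372))
    d1_slack = (index_latest - span_start).days - 365 - 7
    d1 = span_start + dt.timedelta(days=365) + _days(rng, 0, min(200, d1_slack))
    gap = _days(rng, 7, min(300, (index_latest - d1).days))
    d2 = d1 + gap
    tl.enrollment.append(EnrollmentSpan(tl.pid, span_start, end))
    spec1 = Specialty.RHEUMATOLOGIST if rheumatologist else Specialty.INTERNIST
    spec2 = _pick(rng, [Specialty.INTERNIST, Specialty.OTHER, Specialty.RHEUMATOLOGIST])
    if not rheumatologist and spec2 is Specialty.RHEUMATOLOGIST:
        spec2 = Specialty.OTHER
    for date, spec in [(d1, spec1), (d2, spec2)]:
        code, system = _ra_code(date, rng)
        tl.diagnoses.append(
            DiagnosisEvent(tl.pid, date, code, system, Setting.OUTPATIENT, 1, spec)
        )
    name, cls = _pick(rng, _DMARDS)
    dmard_date = d1 + _days(rng, 0, max((d2 - d1).days, 1))
    if dmard_date > d2:
        dmard_date = d2
    tl.drugs.append(DrugEvent(tl.pid, dmard_date, cls, name))
    return d2


def plant_incident_ild(
    tl: _Timeline,
    rng: np.random.Generator,
    onset: dt.date,
    category: CaseCategory,
    with_accrual: bool = True,
) -> None:
    """Plant a case-qualifying ILD diagnosis at ``onset`` with its anchors.

    Accrual codes (broad-screen codes from non-qualifying providers) may be
    sprinkled inside the 183-day window before onset; they neither qualify a
    case earlier nor disqualify the incident classification.
    """
    code, system = _ild_code(onset, rng)
    if category is CaseCategory.HOSPITAL_PRIMARY:
        tl.diagnoses.append(
            DiagnosisEvent(tl.pid, onset, code, system, Setting.INPATIENT, 1, Specialty.OTHER)
        )
    elif category is CaseCategory.HOSPITAL_NON_PRIMARY:
        tl.diagnoses.append(
            DiagnosisEvent(
                tl.pid, onset, code, system, Setting.INPATIENT, int(rng.integers(2, 6)), Specialty.OTHER
            )
        )
    else:
        specialty = _pick(
            rng, [Specialty.PULMONOLOGIST, Specialty.RHEUMATOLOGIST, Specialty.INTERNIST]
        )
        tl.diagnoses.append(
            DiagnosisEvent(tl.pid, onset, code, system, Setting.OUTPATIENT, 1, specialty)
        )
        anchor = onset - _days(rng, 0, 90)
        if category is CaseCategory.OUTPATIENT_CT:
            kind = _pick(rng, [ProcedureKind.CHEST_CT, ProcedureKind.CHEST_CT, ProcedureKind.LUNG_BIOPSY])
            tl.procedures.append(ProcedureEvent(tl.pid, anchor, kind, Setting.OUTPATIENT))
        else:
            admit = anchor - _days(rng, 1, 10)
            tl.stays.append(HospitalStay(tl.pid, admit, anchor))
    if with_accrual:
        for _ in range(int(rng.integers(0, 3))):
            acc_date = onset - _days(rng, 1, 182)
            acc_code, acc_system = _sensitive_code(acc_date, rng)
            tl.diagnoses.append(
                DiagnosisEvent(
                    tl.pid, acc_date, acc_code, acc_system, Setting.OUTPATIENT, 1, Specialty.OTHER
                )
            )


def plant_confuser(
    tl: _Timeline,
    rng: np.random.Generator,
    kind: str,
    index: dt.date,
    data_end: dt.date,
) -> dt.date | None:
    """Plant events that must NOT yield an incident classification.

    ``prevalent_ild``: early specific-ILD evidence plus a later qualifying
    diagnosis — detected as a case, classified prevalent.  ``sarcoidosis``:
    a sarcoid code inside the post-index clean year plus a later qualifying
    diagnosis.  ``copd_bronchiectasis``: broad-screen noise only — a screen
    hit but never a case.  Returns the planted case-qualifying date, if any.
    """
    if kind == "prevalent_ild":
        evidence = index - _days(rng, 400, 700)
        code, system = _ild_code(evidence, rng)
        tl.diagnoses.append(
            DiagnosisEvent(tl.pid, evidence, code, system, Setting.OUTPATIENT, 1, Specialty.OTHER)
        )
        case_date = index + _days(rng, 250, 364)
        plant_incident_ild(tl, rng, case_date, CaseCategory.OUTPATIENT_CT, with_accrual=False)
        return case_date
    if kind == "sarcoidosis":
        # sarcoid must land inside the clean window: <= min(index+365, case-183)
        sar_date = index + _days(rng, 10, 260)
        code, system = _sarcoid_code(sar_date)
        tl.diagnoses.append(
            DiagnosisEvent(tl.pid, sar_date, code, system, Setting.OUTPATIENT, 1, Specialty.OTHER)
        )
        case_date = index + _days(rng, 450, 600)
        if case_date > data_end:
            case_date = data_end
        plant_incident_ild(tl, rng, case_date, CaseCategory.HOSPITAL_NON_PRIMARY, with_accrual=False)
        return case_date
    if kind == "copd_bronchiectasis":
        for _ in range(int(rng.integers(1, 4))):
            date = index + _days(rng, 10, 500)
            if date > data_end:
                date = data_end
            code, system = _sensitive_code(date, rng)
            tl.diagnoses.append(
                DiagnosisEvent(tl.pid, date, code, system, Setting.OUTPATIENT, 1, Specialty.OTHER)
            )
        return None
    raise ValueError(f"unknown confuser kind: {kind}")


def _plant_near_miss(
    tl: _Timeline,
    rng: np.random.Generator,
    variant: NearMiss,
    start: dt.date,
    end: dt.date,
) -> TruthLabel:
    """One patient violating exactly one rule; truth says what must be rejected."""
    pid = tl.pid
    if variant is NearMiss.RA_PAIR_6_DAYS:
        span_start = start + _days(rng, 0, 200)
        tl.enrollment.append(EnrollmentSpan(pid, span_start, end))
        d1 = span_start + dt.timedelta(days=365) + _days(rng, 0, 200)
        d2 = d1 + dt.timedelta(days=6)  # one day short of the 7-day minimum
        for date, spec in [(d1, Specialty.RHEUMATOLOGIST), (d2, Specialty.INTERNIST)]:
            code, system = _ra_code(date, rng)
            tl.diagnoses.append(
                DiagnosisEvent(pid, date, code, system, Setting.OUTPATIENT, 1, spec)
            )
        tl.drugs.append(DrugEvent(pid, d1, DrugClass.CSDMARD, "methotrexate"))
        return TruthLabel(pid, is_ra=False, near_miss=variant)
    if variant is NearMiss.NO_RHEUMATOLOGIST:
        _plant_ra_qualification(tl, rng, start, end, end - dt.timedelta(days=400), rheumatologist=False)
        return TruthLabel(pid, is_ra=False, near_miss=variant)
    if variant is NearMiss.COVERAGE_GAP:
        span_start = start + _days(rng, 0, 200)
        d1 = span_start + dt.timedelta(days=365) + _days(rng, 30, 120)
        gap_days = _days(rng, 30, 200)
        d2 = d1 + gap_days
        # one uncovered day inside the coverage window ending at d2; the
        # post-gap span stays under a full coverage year so the requirement
        # is never met later either
        gap_day = d2 - _days(rng, gap_days.days + 5, 364)
        tl.enrollment.append(EnrollmentSpan(pid, span_start, gap_day - dt.timedelta(days=1)))
        tl.enrollment.append(
            EnrollmentSpan(pid, gap_day + dt.timedelta(days=1), gap_day + _days(rng, 100, 360))
        )
        for date, spec in [(d1, Specialty.RHEUMATOLOGIST), (d2, Specialty.INTERNIST)]:
            code, system = _ra_code(date, rng)
            tl.diagnoses.append(
                DiagnosisEvent(pid, date, code, system, Setting.OUTPATIENT, 1, spec)
            )
        tl.drugs.append(DrugEvent(pid, d2, DrugClass.CSDMARD, "methotrexate"))
        return TruthLabel(pid, is_ra=False, near_miss=variant)
    if variant is NearMiss.PART_C_SPELL:
        span_start = start + _days(rng, 0, 200)
        d1 = span_start + dt.timedelta(days=365) + _days(rng, 30, 120)
        gap_days = _days(rng, 30, 200)
        d2 = d1 + gap_days
        # one managed-care (Part C) day inside the coverage window ending at d2
        c_day = d2 - _days(rng, gap_days.days + 5, 364)
        tl.enrollment.append(EnrollmentSpan(pid, span_start, c_day - dt.timedelta(days=1)))
        tl.enrollment.append(EnrollmentSpan(pid, c_day, c_day, part_c=True))
        tl.enrollment.append(
            EnrollmentSpan(pid, c_day + dt.timedelta(days=1), c_day + _days(rng, 100, 360))
        )
        for date, spec in [(d1, Specialty.RHEUMATOLOGIST), (d2, Specialty.INTERNIST)]:
            code, system = _ra_code(date, rng)
            tl.diagnoses.append(
                DiagnosisEvent(pid, date, code, system, Setting.OUTPATIENT, 1, spec)
            )
        tl.drugs.append(DrugEvent(pid, d2, DrugClass.CSDMARD, "methotrexate"))
        return TruthLabel(pid, is_ra=False, near_miss=variant)
    if variant is NearMiss.CT_91_DAYS:
        index = _plant_ra_qualification(tl, rng, start, end, end - dt.timedelta(days=600))
        dx_date = index + _days(rng, 100, 400)
        code, system = _ild_code(dx_date, rng)
        tl.diagnoses.append(
            DiagnosisEvent(
                pid, dx_date, code, system, Setting.OUTPATIENT, 1, Specialty.PULMONOLOGIST
            )
        )
        tl.procedures.append(
            ProcedureEvent(
                pid, dx_date - dt.timedelta(days=91), ProcedureKind.CHEST_CT, Setting.OUTPATIENT
            )
        )
        return TruthLabel(pid, is_ra=True, ra_true_index=index, near_miss=variant)
    if variant is NearMiss.BASELINE_SARCOIDOSIS:
        index = _plant_ra_qualification(tl, rng, start, end, end - dt.timedelta(days=800))
        sar_date = index - _days(rng, 30, 300)
        code, system = _sarcoid_code(sar_date)
        tl.diagnoses.append(
            DiagnosisEvent(pid, sar_date, code, system, Setting.OUTPATIENT, 1, Specialty.OTHER)
        )
        onset = index + _days(rng, 400, 700)
        if onset > end:
            onset = end
        plant_incident_ild(tl, rng, onset, CaseCategory.OUTPATIENT_CT, with_accrual=False)
        return TruthLabel(
            pid,
            is_ra=True,
            ra_true_index=index,
            ild_status=ILDStatus.MIMIC,
            ild_true_onset=onset,
            planted_category=CaseCategory.OUTPATIENT_CT,
            near_miss=variant,
        )
    raise ValueError(variant)


def generate(scenario: SimulationScenario) -> tuple[ClaimsBundle, list[TruthLabel]]:
    """Generate a claims bundle plus per-patient truth labels.

    Patients are assigned roles from the scenario proportions: near-miss
    variants first, then RA vs non-RA, and among RA patients prevalent ILD,
    mimics, and incident ILD (incidence converted to a per-patient
    probability via each patient's post-index follow-up years).
    """
    rng = np.random.default_rng(scenario.seed)
    start, end = scenario.date_range
    width = len(str(scenario.n_patients))
    labels: list[TruthLabel] = []
    timelines: list[_Timeline] = []

    roles: list[tuple[str, NearMiss | None]] = []
    for variant_name, rate in sorted(scenario.near_miss_rates.items()):
        count = int(round(rate * scenario.n_patients))
        roles += [("near_miss", NearMiss(variant_name))] * count
    remaining = scenario.n_patients - len(roles)
    if remaining < 0:
        raise ValueError("near_miss_rates sum to more than the whole population")
    n_ra = int(round(scenario.fraction_ra * remaining))
    roles += [("ra", None)] * n_ra + [("non_ra", None)] * (remaining - n_ra)

    for i, (role, variant) in enumerate(roles):
        pid = f"P{i + 1:0{width}d}"
        tl = _Timeline(pid)
        if role == "near_miss":
            labels.append(_plant_near_miss(tl, rng, variant, start, end))
        elif role == "non_ra":
            # background patient: coverage plus unrelated outpatient noise
            span_start = start + _days(rng, 0, 365)
            tl.enrollment.append(EnrollmentSpan(pid, span_start, end))
            for _ in range(int(rng.integers(1, 4))):
                date = span_start + _days(rng, 0, max((end - span_start).days, 1))
                if date > end:
                    date = end
                code, system = (
                    ("250.00", CodeSystem.ICD9CM)
                    if date < ICD10_SWITCH
                    else ("E11.9", CodeSystem.ICD10CM)
                )
                tl.diagnoses.append(
                    DiagnosisEvent(pid, date, code, system, Setting.OUTPATIENT, 1, Specialty.OTHER)
                )
            labels.append(TruthLabel(pid, is_ra=False))
        else:
            index = _plant_ra_qualification(
                tl, rng, start, end, end - dt.timedelta(days=800)
            )
            follow_years = max((end - index).days, 0) / 365.25
            u = rng.random()
            p_prev = scenario.fraction_prevalent_ild
            p_mimic = scenario.fraction_mimics
            p_inc = min(1.0, scenario.ild_incidence_rate * follow_years / 1000.0)
            if u < p_prev and (index - start).days >= 700:
                case_date = plant_confuser(tl, rng, "prevalent_ild", index, end)
                labels.append(
                    TruthLabel(
                        pid,
                        is_ra=True,
                        ra_true_index=index,
                        ild_status=ILDStatus.PREVALENT,
                        ild_true_onset=case_date,
                        planted_category=CaseCategory.OUTPATIENT_CT,
                    )
                )
            elif u < p_prev + p_mimic:
                mimic_kind = _pick(rng, ["sarcoidosis", "copd_bronchiectasis"])
                onset = plant_confuser(tl, rng, mimic_kind, index, end)
                labels.append(
                    TruthLabel(
                        pid,
                        is_ra=True,
                        ra_true_index=index,
                        ild_status=ILDStatus.MIMIC,
                        ild_true_onset=onset,
                        planted_category=(
                            CaseCategory.HOSPITAL_NON_PRIMARY if mimic_kind == "sarcoidosis" else None
                        ),
                    )
                )
            elif u < p_prev + p_mimic + p_inc:
                onset = index + _days(rng, 184, max((end - index).days, 185))
                if onset > end:
                    onset = end
                category = _pick(rng, list(CaseCategory))
                plant_incident_ild(tl, rng, onset, category)
                labels.append(
                    TruthLabel(
                        pid,
                        is_ra=True,
                        ra_true_index=index,
                        ild_status=ILDStatus.INCIDENT,
                        ild_true_onset=onset,
                        planted_category=category,
                    )
                )
            else:
                labels.append(TruthLabel(pid, is_ra=True, ra_true_index=index))
        timelines.append(tl)

    bundle = ClaimsBundle(
        diagnoses=tuple(d for tl in timelines for d in tl.diagnoses),
        procedures=tuple(p for tl in timelines for p in tl.procedures),
        drugs=tuple(d for tl in timelines for d in tl.drugs),
        enrollment=tuple(s for tl in timelines for s in tl.enrollment),
        stays=tuple(s for tl in timelines for s in tl.stays),
        data_start=start,
        data_end=end,
    )
    return bundle, labels


def synthesize_adjudications(
    labels: Sequence[TruthLabel],
    case_patient_ids: Sequence[str],
    seed: int,
    not_confirmed_rate: float = 0.0,
    insufficient_rate: float = 0.0,
) -> list[AdjudicationRecord]:
    """Derive chart-review outcomes from planted truth for detected cases.

    A true-ILD case is confirmed (flipped to not-confirmed with
    ``not_confirmed_rate``, emulating adjudication disagreement); mimics
    and false positives are not confirmed; a fraction is marked
    insufficient-information.  Onset dates echo the planted truth.
    """
    rng = np.random.default_rng(seed)
    by_pid = {t.patient_id: t for t in labels}
    records = []
    for pid in case_patient_ids:
        truth = by_pid[pid]
        if rng.random() < insufficient_rate:
            records.append(AdjudicationRecord(pid, AdjudicationOutcome.INSUFFICIENT))
            continue
        truly_ild = truth.ild_status in (ILDStatus.INCIDENT, ILDStatus.PREVALENT)
        if truly_ild and rng.random() >= not_confirmed_rate:
            records.append(
                AdjudicationRecord(
                    pid,
                    AdjudicationOutcome.CONFIRMED,
                    IncidenceClass.INCIDENT
                    if truth.ild_status is ILDStatus.INCIDENT
                    else IncidenceClass.PREVALENT,
                    onset_date=truth.ild_true_onset,
                )
            )
        else:
            records.append(AdjudicationRecord(pid, AdjudicationOutcome.NOT_CONFIRMED))
    return records
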