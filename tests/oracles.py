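"""Independent brute-force oracles for the window logic.

These re-derive cohort membership, case qualification, and incident
classification by day-by-day / pairwise enumeration, deliberately sharing
no code with the package's scanning implementations.
"""

from __future__ import annotations

import datetime as dt

from raild.codesets import CodeRegistry
from raild.model import ClaimsBundle, ProcedureKind, Setting, Specialty
from raild.params import AlgorithmParams

ONE_DAY = dt.timedelta(days=1)


def covered_days(spans, gap_tolerance_days=0):
    """Set of dates covered by qualifying (A+B, no C) enrollment, with gaps
    up to the tolerance bridged by enumeration."""
    days = set()
    for s in spans:
        if s.part_a and s.part_b and not s.part_c:
            d = s.start_date
            while d <= s.end_date:
                days.add(d)
                d += ONE_DAY
    if gap_tolerance_days and days:
        out = set(days)
        for d in sorted(days):
            for k in range(1, gap_tolerance_days + 1):
                probe = d + dt.timedelta(days=k)
                if probe in days:
                    break
                out.add(probe)  # speculative bridge; trimmed below
        # a bridged day only stands if a covered day follows within tolerance
        out = {
            d
            for d in out
            if d in days
            or any(d + dt.timedelta(days=k) in days for k in range(1, gap_tolerance_days + 1))
        }
        return out
    return days


def coverage_ok_on(days, as_of, window_days):
    probe = as_of - dt.timedelta(days=window_days - 1)
    while probe <= as_of:
        if probe not in days:
            return False
        probe += ONE_DAY
    return True


def brute_cohort_member(patient: ClaimsBundle, pid: str, registry: CodeRegistry,
                        params: AlgorithmParams):
    """Earliest day on which all cohort requirements hold, or None.

    Scans every calendar day of the data window and checks, from scratch:
    a valid diagnosis pair fully on/before that day, a DMARD on/before it,
    and a fully covered trailing coverage window.  Baseline exclusions are
    then applied strictly before the found index.
    """
    ra_dx = [d for d in patient.diagnoses if registry.is_ra(d.code, d.code_system)]
    dmards = [d.service_date for d in patient.drugs if d.drug_class.value.endswith("DMARD")]
    if not dmards:
        return None
    pair_days = set()
    for a in ra_dx:
        for b in ra_dx:
            gap = (b.service_date - a.service_date).days
            if params.ra_pair_min_days <= gap <= params.ra_pair_max_days and (
                a.specialty is Specialty.RHEUMATOLOGIST or b.specialty is Specialty.RHEUMATOLOGIST
            ):
                pair_days.add(b.service_date)
    if not pair_days:
        return None
    window = params.baseline_coverage_months * 365 // 12
    days = covered_days(patient.enrollment, params.coverage_gap_tolerance_days)
    clinical_ready = max(min(pair_days), min(dmards))
    # walk the calendar once, tracking the streak of consecutive covered days
    d = min([patient.data_start, *days]) if days else patient.data_start
    streak = 0
    while d <= patient.data_end:
        streak = streak + 1 if d in days else 0
        if d >= clinical_ready and streak >= window:
            excluded = any(
                e.service_date < d and registry.is_baseline_exclusion(e.code, e.code_system)
                for e in patient.diagnoses
            )
            return None if excluded else d
        d += ONE_DAY
    return None


def brute_qualifies(patient: ClaimsBundle, dx, params: AlgorithmParams):
    """Category of a diagnosis by explicit enumeration of anchor offsets."""
    if dx.setting is Setting.INPATIENT:
        return "HospitalPrimary" if dx.position == 1 else "HospitalNonPrimary"
    if dx.specialty not in (
        Specialty.PULMONOLOGIST,
        Specialty.RHEUMATOLOGIST,
        Specialty.INTERNIST,
    ):
        return None
    for off in range(0, params.ct_anchor_window_days + 1):
        anchor_day = dx.service_date - dt.timedelta(days=off)
        for p in patient.procedures:
            if (
                p.setting is Setting.OUTPATIENT
                and p.kind in (ProcedureKind.CHEST_CT, ProcedureKind.LUNG_BIOPSY)
                and p.service_date == anchor_day
            ):
                return "OutpatientCT"
    for off in range(0, params.hosp_anchor_window_days + 1):
        anchor_day = dx.service_date - dt.timedelta(days=off)
        for s in patient.stays:
            anchor = s.discharge_date if params.hospital_anchor == "discharge" else s.admit_date
            if anchor == anchor_day:
                return "OutpatientHospital"
    return None


def brute_incident(patient: ClaimsBundle, index: dt.date, case_date: dt.date,
                   registry: CodeRegistry, params: AlgorithmParams):
    """Day-by-day clean-window scan; returns 'incident'/'prevalent_or_unclear'/
    'unclassifiable'."""
    if (index - patient.data_start).days < params.baseline_coverage_months * 365 // 12:
        return "unclassifiable"
    end = min(
        index + dt.timedelta(days=params.incident_post_index_clean_days),
        case_date - dt.timedelta(days=params.incident_accrual_days),
    )
    d = patient.data_start
    while d <= end:
        for e in patient.diagnoses:
            if e.service_date == d and registry.is_incident_disqualifier(e.code, e.code_system):
                return "prevalent_or_unclear"
        for p in patient.procedures:
            if p.service_date == d and p.kind is ProcedureKind.LUNG_BIOPSY:
                return "prevalent_or_unclear"
        d += ONE_DAY
    return "incident"
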