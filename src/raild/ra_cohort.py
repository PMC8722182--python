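"""RA cohort identification from claims streams.

A patient enters the RA cohort when all three requirements are met:

1. Two RA diagnosis claims (ICD-9-CM 714.0 / 714.2, or a configured
   ICD-10-era equivalent) 7–365 days apart (inclusive), at least one of the
   pair billed by a rheumatologist.
2. At least one prescription or infusion of a DMARD (conventional,
   biologic, or targeted-synthetic).
3. At least 12 months of continuous Medicare Part A + Part B coverage with
   no Part C enrollment, measured up to the start of follow-up.

The cohort index date is the latest of the three component dates — the day
the patient first satisfies everything simultaneously.  Patients with a
baseline diagnosis of another autoimmune disease, malignancy other than
non-melanoma skin cancer, HIV, or organ transplantation (any time strictly
before the index date, using all available data) are excluded.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

from .codesets import CodeRegistry
from .model import (
    ClaimsBundle,
    DiagnosisEvent,
    DrugEvent,
    DMARD_CLASSES,
    EnrollmentSpan,
    Specialty,
)
from .params import AlgorithmParams

#: whole-day window length used for "n months" of coverage; 12 months = 365 days
DAYS_PER_COVERAGE_YEAR = 365


def _months_to_days(months: int) -> int:
    return months * DAYS_PER_COVERAGE_YEAR // 12


@dataclass(frozen=True)
class CohortMember:
    patient_id: str
    ra_index_date: dt.date
    first_ra_dx_date: dt.date
    second_ra_dx_date: dt.date
    rheum_dx_date: dt.date
    first_dmard_date: dt.date
    coverage_ok_date: dt.date


@dataclass(frozen=True)
class RAQualification:
    """Evidence for the diagnosis-pair + DMARD part of cohort entry."""

    first_ra_dx_date: dt.date
    second_ra_dx_date: dt.date
    rheum_dx_date: dt.date
    first_dmard_date: dt.date

    @property
    def met_date(self) -> dt.date:
        return max(self.second_ra_dx_date, self.first_dmard_date)


def _qualifying_spans(
    spans: Iterable[EnrollmentSpan], gap_tolerance_days: int
) -> list[tuple[dt.date, dt.date]]:
    """Merge A+B-without-C spans, bridging gaps up to the tolerance."""
    usable = sorted(
        (s.start_date, s.end_date)
        for s in spans
        if s.part_a and s.part_b and not s.part_c and s.start_date <= s.end_date
    )
    merged: list[tuple[dt.date, dt.date]] = []
    for start, end in usable:
        if merged and (start - merged[-1][1]).days <= gap_tolerance_days + 1:
            prev_start, prev_end = merged[-1]
            merged[-1] = (prev_start, max(prev_end, end))
        else:
            merged.append((start, end))
    return merged


def continuous_coverage_ok(
    spans: Iterable[EnrollmentSpan],
    as_of: dt.date,
    months: int = 12,
    gap_tolerance_days: int = 0,
) -> tuple[bool, dt.date | None]:
    """Is every day of the ``months``-month window ending at ``as_of`` covered?

    The window is the closed interval of ``months * 365 // 12`` days ending
    at ``as_of``.  Coverage means enrollment with Part A and Part B and no
    Part C; gaps up to ``gap_tolerance_days`` are bridged (default 0:
    strictly continuous).  Returns ``(ok, earliest_date)`` where
    ``earliest_date`` is the first date at which the requirement could ever
    be satisfied given these spans (``None`` if never).
    """
    window = _months_to_days(months)
    merged = _qualifying_spans(spans, gap_tolerance_days)
    earliest: dt.date | None = None
    ok = False
    for start, end in merged:
        span_days = (end - start).days + 1
        if span_days >= window:
            candidate = start + dt.timedelta(days=window - 1)
            if earliest is None or candidate < earliest:
                earliest = candidate
        window_start = as_of - dt.timedelta(days=window - 1)
        if start <= window_start and end >= as_of:
            ok = True
    return ok, earliest


def earliest_coverage_on_or_after(
    spans: Iterable[EnrollmentSpan],
    floor: dt.date,
    months: int = 12,
    gap_tolerance_days: int = 0,
) -> dt.date | None:
    """Earliest date ``d >= floor`` whose trailing coverage window is fully met."""
    window = _months_to_days(months)
    for start, end in _qualifying_spans(spans, gap_tolerance_days):
        candidate = max(start + dt.timedelta(days=window - 1), floor)
        if candidate <= end:
            return candidate
    return None


def find_ra_qualification(
    diagnoses: Sequence[DiagnosisEvent],
    drugs: Sequence[DrugEvent],
    registry: CodeRegistry,
    params: AlgorithmParams = AlgorithmParams(),
) -> RAQualification | None:
    """Find the earliest qualifying RA diagnosis pair plus first DMARD.

    Scans all RA-coded diagnoses for a pair ``d1 < d2`` with
    ``ra_pair_min_days <= d2 - d1 <= ra_pair_max_days`` (closed interval) and
    at least one member billed by a rheumatologist.  Among valid pairs the
    one with the earliest second date wins (ties: earliest first date), so
    the qualification date is as early as the data allows.  Returns ``None``
    if no valid pair or no DMARD exists.
    """
    ra_dx = sorted(
        (d for d in diagnoses if registry.is_ra(d.code, d.code_system)),
        key=lambda d: d.service_date,
    )
    dmard_dates = sorted(
        d.service_date for d in drugs if d.drug_class in DMARD_CLASSES
    )
    if not dmard_dates:
        return None

    best: tuple[dt.date, dt.date, dt.date] | None = None  # (d2, d1, rheum_date)
    for i, d1 in enumerate(ra_dx):
        for d2 in ra_dx[i + 1 :]:
            gap = (d2.service_date - d1.service_date).days
            if gap < params.ra_pair_min_days:
                continue
            if gap > params.ra_pair_max_days:
                break  # ra_dx sorted: later partners only get farther
            rheum = [
                e.service_date
                for e in (d1, d2)
                if e.specialty is Specialty.RHEUMATOLOGIST
            ]
            if not rheum:
                continue
            key = (d2.service_date, d1.service_date, min(rheum))
            if best is None or key < best:
                best = key
    if best is None:
        return None
    d2_date, d1_date, rheum_date = best
    return RAQualification(
        first_ra_dx_date=d1_date,
        second_ra_dx_date=d2_date,
        rheum_dx_date=rheum_date,
        first_dmard_date=dmard_dates[0],
    )


def apply_baseline_exclusions(
    diagnoses: Sequence[DiagnosisEvent],
    registry: CodeRegistry,
    index_date: dt.date,
) -> tuple[bool, list[str]]:
    """Check baseline exclusion diagnoses strictly before the index date.

    All available pre-index data is scanned; a code on the index date itself
    does not exclude (strictly-before convention).  Returns
    ``(excluded, reasons)`` where each reason names the triggering code.
    """
    reasons = []
    for d in diagnoses:
        if d.service_date >= index_date:
            continue
        if registry.is_baseline_exclusion(d.code, d.code_system):
            cls = registry.classify(d.code, d.code_system)
            reasons.append(
                f"{cls.value} code {d.code} ({d.code_system.value}) "
                f"on {d.service_date.isoformat()}"
            )
    return bool(reasons), reasons


def build_ra_cohort(
    bundle: ClaimsBundle,
    registry: CodeRegistry,
    params: AlgorithmParams = AlgorithmParams(),
) -> list[CohortMember]:
    """Apply the full cohort rule to every patient in the bundle.

    The index date is ``max(second RA dx date, first DMARD date, coverage
    satisfaction date)``; if coverage has lapsed by the time the clinical
    requirements are met, the index moves to the next date at which the
    trailing coverage window is again complete.  Output is ordered by
    patient_id.
    """
    members: list[CohortMember] = []
    by_patient_dx: dict[str, list[DiagnosisEvent]] = {}
    for d in bundle.diagnoses:
        by_patient_dx.setdefault(d.patient_id, []).append(d)
    by_patient_drug: dict[str, list[DrugEvent]] = {}
    for d in bundle.drugs:
        by_patient_drug.setdefault(d.patient_id, []).append(d)
    by_patient_span: dict[str, list[EnrollmentSpan]] = {}
    for s in bundle.enrollment:
        by_patient_span.setdefault(s.patient_id, []).append(s)

    for pid in bundle.patient_ids():
        dx = by_patient_dx.get(pid, [])
        qual = find_ra_qualification(dx, by_patient_drug.get(pid, []), registry, params)
        if qual is None:
            continue
        spans = by_patient_span.get(pid, [])
        base = qual.met_date
        ok, earliest = continuous_coverage_ok(
            spans, base, params.baseline_coverage_months, params.coverage_gap_tolerance_days
        )
        if ok:
            index = base
            coverage_date = earliest if earliest is not None else base
        else:
            later = earliest_coverage_on_or_after(
                spans, base, params.baseline_coverage_months, params.coverage_gap_tolerance_days
            )
            if later is None:
                continue
            index = later
            coverage_date = later
        excluded, _ = apply_baseline_exclusions(dx, registry, index)
        if excluded:
            continue
        members.append(
            CohortMember(
                patient_id=pid,
                ra_index_date=index,
                first_ra_dx_date=qual.first_ra_dx_date,
                second_ra_dx_date=qual.second_ra_dx_date,
                rheum_dx_date=qual.rheum_dx_date,
                first_dmard_date=qual.first_dmard_date,
                coverage_ok_date=coverage_date,
            )
        )
    return members
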