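"""Validation statistics for claims-algorithm performance.

Positive predictive value with exact (Clopper–Pearson) binomial confidence
intervals, sensitivity relative to a broad screen, per-code PPV screening,
incident-classification validation with a ±6-month onset tolerance,
Cohen's kappa for inter-rater agreement, and standardized mean differences
for cohort balance.

The CI method is Clopper–Pearson throughout: the exact interval is the
only binomial interval that behaves at the boundaries this validation runs
into (a category with every case confirmed has p̂ = 1, where normal
approximations degenerate; the exact lower bound for 28/28 is
0.025^(1/28) ≈ 0.877).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import beta

from .ild import CaseCategory, ILDCase, IncidentStatus, ScreenHit
from .model import AdjudicationOutcome, AdjudicationRecord, IncidenceClass


def exact_binomial_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact confidence interval for a binomial proportion.

    ``lower = Beta(α/2; x, n−x+1)`` and ``upper = Beta(1−α/2; x+1, n−x)``
    quantiles, with the conventional boundary values ``lower = 0`` at
    ``x = 0`` and ``upper = 1`` at ``x = n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


@dataclass(frozen=True)
class ValidationRow:
    """One stratum of a PPV table: algorithm-positive counts vs adjudication."""

    stratum: str
    tp: int
    fp: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fp == 0:
            raise ValueError(f"stratum {self.stratum!r}: PPV undefined for 0 positives")

    @property
    def n(self) -> int:
        return self.tp + self.fp

    @property
    def ppv(self) -> float:
        return self.tp / self.n

    @property
    def ci(self) -> tuple[float, float]:
        return exact_binomial_ci(self.tp, self.n, self.level)

    def formatted(self) -> str:
        lo, hi = self.ci
        return (
            f"{self.stratum}: {self.tp}/{self.n} = {round(100 * self.ppv)}% "
            f"({round(100 * lo)}%, {round(100 * hi)}%)"
        )


def ppv(tp: int, fp: int, level: float = 0.95, stratum: str = "all") -> ValidationRow:
    """PPV = tp / (tp + fp), with its exact CI, as a table row."""
    return ValidationRow(stratum=stratum, tp=tp, fp=fp, level=level)


def sensitivity_vs_screen(
    algorithm_confirmed: int, screen_confirmed: int, level: float = 0.95
) -> ValidationRow:
    """Sensitivity of the final algorithm relative to the broad screen.

    This is sensitivity over the screened-and-adjudicated set — confirmed
    cases the final algorithm retained divided by all confirmed cases the
    broad screen surfaced — not population sensitivity, which claims data
    alone cannot measure.
    """
    if screen_confirmed < 1:
        raise ValueError("screen_confirmed must be >= 1")
    if algorithm_confirmed > screen_confirmed:
        raise ValueError("algorithm cannot confirm more than the screen surfaced")
    return ValidationRow(
        stratum="sensitivity_vs_screen",
        tp=algorithm_confirmed,
        fp=screen_confirmed - algorithm_confirmed,
        level=level,
    )


def per_code_ppv(
    screen_hits: Mapping[str, ScreenHit],
    adjudications: Iterable[AdjudicationRecord],
    level: float = 0.95,
) -> list[ValidationRow]:
    """PPV per screening code, attributing each patient to their FIRST code.

    Patients with outcomes other than confirmed / not-confirmed (adjudication
    impossible) are left out; codes with no adjudicated patients are absent.
    Rows are ordered by descending n, then code.
    """
    outcomes = {a.patient_id: a.outcome for a in adjudications}
    counts: dict[str, list[int]] = {}
    for pid, hit in screen_hits.items():
        outcome = outcomes.get(pid)
        if outcome is AdjudicationOutcome.CONFIRMED:
            counts.setdefault(hit.code, [0, 0])[0] += 1
        elif outcome is AdjudicationOutcome.NOT_CONFIRMED:
            counts.setdefault(hit.code, [0, 0])[1] += 1
    rows = [
        ValidationRow(stratum=code, tp=tp, fp=fp, level=level)
        for code, (tp, fp) in counts.items()
    ]
    rows.sort(key=lambda r: (-r.n, r.stratum))
    return rows


@dataclass(frozen=True)
class IncidentValidationRow:
    """Incident-algorithm performance in one case-qualifying stratum.

    ``conditional`` PPV asks: among algorithm-incident cases confirmed as
    ILD, how many were truly incident?  ``unconditional`` PPV adds the
    not-ILD cases to the denominator, measuring the incident algorithm
    end to end.
    """

    stratum: str
    incident_confirmed: int
    prevalent_confirmed: int
    not_ild: int
    level: float = 0.95

    @property
    def any_ild(self) -> int:
        return self.incident_confirmed + self.prevalent_confirmed

    @property
    def total(self) -> int:
        return self.any_ild + self.not_ild

    @property
    def conditional(self) -> ValidationRow | None:
        if self.any_ild == 0:
            return None
        return ValidationRow(
            stratum=f"{self.stratum}|confirmed",
            tp=self.incident_confirmed,
            fp=self.prevalent_confirmed,
            level=self.level,
        )

    @property
    def unconditional(self) -> ValidationRow | None:
        if self.total == 0:
            return None
        return ValidationRow(
            stratum=f"{self.stratum}|all",
            tp=self.incident_confirmed,
            fp=self.prevalent_confirmed + self.not_ild,
            level=self.level,
        )


def incident_validation(
    cases: Sequence[ILDCase],
    adjudications: Iterable[AdjudicationRecord],
    tolerance_days: int = 183,
    level: float = 0.95,
) -> list[IncidentValidationRow]:
    """Validate algorithm-incident cases against adjudicated onset dates.

    Only algorithm-incident cases enter.  A case counts as correctly
    incident iff adjudicated incident AND the chart onset date lies within
    ``tolerance_days`` of the claims case date (adjudications lacking an
    onset date fall back to the incidence class alone).  Returns one row
    per case-qualifying category, an ``All definitions`` roll-up, and a
    ``Without HospitalNonPrimary`` roll-up.
    """
    adj = {a.patient_id: a for a in adjudications}
    counts: dict[str, list[int]] = {c.value: [0, 0, 0] for c in CaseCategory}
    for case in cases:
        if case.incident is not IncidentStatus.INCIDENT:
            continue
        record = adj.get(case.patient_id)
        if record is None or record.outcome in (
            AdjudicationOutcome.INSUFFICIENT,
            AdjudicationOutcome.NOT_RETRIEVABLE,
        ):
            continue
        slot = counts[case.qualification.category.value]
        if record.outcome is AdjudicationOutcome.NOT_CONFIRMED:
            slot[2] += 1
        elif record.incidence_class is IncidenceClass.INCIDENT and _onset_ok(
            record.onset_date, case.case_date, tolerance_days
        ):
            slot[0] += 1
        else:
            slot[1] += 1

    def row(name: str, cats: Iterable[CaseCategory]) -> IncidentValidationRow:
        inc = sum(counts[c.value][0] for c in cats)
        prev = sum(counts[c.value][1] for c in cats)
        neg = sum(counts[c.value][2] for c in cats)
        return IncidentValidationRow(name, inc, prev, neg, level)

    rows = [row(c.value, [c]) for c in CaseCategory]
    rows.append(row("All definitions", list(CaseCategory)))
    rows.append(
        row(
            "Without HospitalNonPrimary",
            [c for c in CaseCategory if c is not CaseCategory.HOSPITAL_NON_PRIMARY],
        )
    )
    return rows


def _onset_ok(onset: dt.date | None, case_date: dt.date, tolerance_days: int) -> bool:
    if onset is None:
        return True  # fall back to the adjudicated incidence class alone
    return abs((onset - case_date).days) <= tolerance_days


def cohens_kappa(table: Sequence[Sequence[int]], level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Cohen's kappa for a 2×2 two-rater agreement table, with its CI.

    ``κ = (p_o − p_e) / (1 − p_e)``; the CI uses the large-sample standard
    error ``sqrt(p_o (1 − p_o) / (n (1 − p_e)²))``, truncated to [−1, 1].
    Degenerate marginals (``p_e = 1``) make kappa undefined.
    """
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty agreement table")
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if pe == 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1, kappa undefined")
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / (n * (1 - pe) ** 2))
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - level) / 2))
    return kappa, (max(-1.0, kappa - z * se), min(1.0, kappa + z * se))


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary for SMD: a mean/sd pair or a proportion."""

    label: str
    mean: float
    sd: float | None = None  # None marks a binary variable: mean is a proportion

    def variance(self) -> float:
        if self.sd is not None:
            return self.sd**2
        return self.mean * (1.0 - self.mean)


def standardized_mean_difference(groups: Sequence[GroupSummary]) -> float:
    """Maximum pairwise standardized mean difference across ≥2 groups.

    Pairwise SMD = |mean₁ − mean₂| / sqrt((var₁ + var₂) / 2); binary
    variables use p(1−p) variance.  With more than two groups the maximum
    over pairs is returned (a conservative imbalance summary — the value is
    a max, not an omnibus statistic).  Zero pooled variance is an error
    unless the means are also equal (SMD 0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    best = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            g1, g2 = groups[i], groups[j]
            pooled = (g1.variance() + g2.variance()) / 2.0
            diff = abs(g1.mean - g2.mean)
            if pooled <= 0:
                if diff > 0:
                    raise ValueError(
                        f"zero pooled variance with unequal means ({g1.label} vs {g2.label})"
                    )
                continue
            best = max(best, diff / math.sqrt(pooled))
    return best
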