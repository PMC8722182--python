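"""Tunable temporal parameters of the cohort and case-finding rules.

All windows are whole-day counts over closed intervals.  The defaults are
the study rules: an RA diagnosis pair 7–365 days apart, 12 months of
continuous A+B (no C) coverage, 90-day CT / hospitalization anchor windows,
a post-index clean year for incident classification, a 183-day (6-month)
diagnostic accrual window before the case date, and a ±183-day tolerance
when validating incident onset dates against chart review.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import yaml


@dataclass(frozen=True)
class AlgorithmParams:
    ra_pair_min_days: int = 7
    ra_pair_max_days: int = 365
    baseline_coverage_months: int = 12
    coverage_gap_tolerance_days: int = 0
    ct_anchor_window_days: int = 90
    hosp_anchor_window_days: int = 90
    incident_post_index_clean_days: int = 365
    incident_accrual_days: int = 183
    incident_validation_tolerance_days: int = 183
    two_code_window_days: int = 365
    #: anchor date for hospitalization-anchored outpatient qualification:
    #: "discharge" (a surrogate for an in-hospital CT, which can occur any
    #: time up to discharge) or "admit".
    hospital_anchor: str = "discharge"
    #: optional exclusion of cases with prior home-oxygen use (a prevalent-ILD
    #: proxy); off by default because it did not change any case disposition.
    home_oxygen_exclusion: bool = False
    #: require a second outpatient ILD code within two_code_window_days for
    #: outpatient-qualified cases.
    two_code_variant: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool) or not isinstance(v, int):
                continue
            if v < 0 or (f.name != "coverage_gap_tolerance_days" and v == 0):
                raise ValueError(f"{f.name} must be positive, got {v}")
        if self.ra_pair_min_days >= self.ra_pair_max_days:
            raise ValueError("ra_pair_min_days must be < ra_pair_max_days")
        if self.hospital_anchor not in ("discharge", "admit"):
            raise ValueError("hospital_anchor must be 'discharge' or 'admit'")


def load_params(config: str | Path | Mapping | None = None) -> AlgorithmParams:
    """Load parameters from a YAML file or mapping; ``None`` gives defaults."""
    if config is None:
        return AlgorithmParams()
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    return AlgorithmParams(**dict(config))
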