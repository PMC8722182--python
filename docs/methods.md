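# Methods

## The phenotyping problem

Administrative claims record diagnoses, procedures, drug dispensings, and
enrollment spells, but no clinical ground truth.  A claims phenotype for
RA-associated interstitial lung disease (RA-ILD) must therefore trade
sensitivity against positive predictive value using only the structure of
the claims: where a diagnosis was made (inpatient vs outpatient, claim
position), by whom (specialty), what diagnostic work surrounded it (chest
CT, lung biopsy, hospitalization), and how the evidence is ordered in
time.  `raild` implements the full rule set — RA cohort entry, ILD case
finding, incident/prevalent separation — plus the statistics used to
validate such rules against chart review, and a simulator that plants
known truth so the rules can be tested mechanically.

## Cohort and case-finding rules

**RA cohort.**  A patient enters the cohort on the first day all three
hold: (1) two RA diagnosis claims (ICD-9-CM 714.0/714.2; the ICD-10-CM M05
family is also accepted so extracts crossing the October 2015 coding
transition behave) separated by 7–365 days inclusive, at least one of the
pair from a rheumatologist; (2) at least one DMARD dispensing
(conventional, biologic, or targeted-synthetic); (3) a complete trailing
coverage window of Part A+B enrollment with no Part C.  The index date is
the maximum of the component dates; if coverage has lapsed when the
clinical requirements are met, the index moves to the next day the
trailing window is again complete.  Baseline exclusions (other autoimmune
disease, malignancy except non-melanoma skin cancer, HIV, transplant)
apply to all data strictly before the index; a code on the index date
itself does not exclude.  The rheumatologist requirement binds to the
qualifying pair, not to any RA claim on record — the strictest literal
reading.

**Case qualification.**  Inpatient ILD diagnoses qualify in any claim
position (primary → `HospitalPrimary`, else `HospitalNonPrimary`).
Outpatient diagnoses qualify only from a pulmonologist, rheumatologist, or
internist, and only when anchored by an outpatient chest CT or lung biopsy
(`OutpatientCT`) or any hospitalization (`OutpatientHospital`) in the
closed window `[dx − 90 d, dx]`; same-day anchors count.  A lung biopsy is
folded into the CT category: both are direct diagnostic anchors, and a
separate biopsy category would be near-empty in practice.  The
hospitalization anchor defaults to the discharge date — a recent
hospitalization stands in for an in-hospital CT, which can occur any time
up to discharge — and is configurable to the admission date.  The case is
the earliest qualifying final-algorithm diagnosis strictly after the RA
index; same-day ties break HospitalPrimary > HospitalNonPrimary >
OutpatientCT > OutpatientHospital, then by code, for determinism.

**Incident classification.**  A case is incident when no *specific* ILD
code, sarcoidosis code (ICD-9-CM 135, ICD-10-CM D86.9), or lung-biopsy
procedure appears in `[data_start, min(index + 365 d, case − 183 d)]`.
The 183-day accrual window before the case date is exempt because an ILD
workup takes months: its codes are part of the diagnosis being made.
Sensitive (broad-screen) codes never disqualify — they are too unspecific
to establish prevalent disease.  Patients with under 12 months of
observable pre-index data are reported as `unclassifiable` rather than
silently dropped.  Prevalent-disease evidence is sought over *all*
available pre-index data (12 months is a floor, not a cap).

**Variants.**  The two-code variant additionally requires a second
outpatient final-algorithm code within 365 days (inclusive) after an
outpatient-qualified case; when a candidate fails, later candidates are
still considered.  The home-oxygen exclusion (prior home O₂ as a
prevalent-ILD proxy) ships off by default: in the source validation it
changed no case disposition.

## Code registry

The registry is fully configuration-driven (YAML) with a documented
default: the final-algorithm set (ICD-9-CM 515, 516.31, 516.34, 516.8,
714.81; ICD-10-CM J84.10, J84.112, J84.9, M05.10) doubles as the
*specific* set used for clean-window disqualification; the *sensitive*
broad-screen set holds the codes that screen well but perform poorly as
case definitions (494.0, 518.89, 793.19, 491.9 and ICD-10 counterparts).
The exhaustive published specific/sensitive partition lives in
supplementary material not reproduced in print, so the default sensitive
set is deliberately partial and user-extensible.  Codes match exactly
after dot-stripping; a trailing `*` marks a family prefix (the
seropositivity proxy is `M05*`).  Classification precedence puts exclusion
classes above ILD classes.  The autoimmune/malignancy exclusion lists are
editable defaults (the source names conditions, not codes): ICD-9 ranges
140–172 and 174–208 for malignancy — 173, non-melanoma skin cancer, is
deliberately absent — plus lupus/scleroderma/myositis, HIV, and transplant
codes in both systems.

## Validation statistics

PPV = tp/(tp+fp) with Clopper–Pearson exact intervals from beta quantiles.
The exact method is the only standard interval that reproduces the
reference tables at their boundary cells — for 28 of 28 the exact lower
bound is 0.025^(1/28) ≈ 0.877 → 88%, where a Wald interval collapses to a
point.  Three published interval cells match no standard binomial method
computed from their own printed counts (the HospitalNonPrimary lower
bound, the Outpatient roll-up interval, and the 45/47 conditional upper
bound); `replay_validation_tables` flags exactly these, and reports the
computed intervals.  Sensitivity is reported *relative to the
screened-and-adjudicated set*, not the population: claims alone cannot see
cases the broad screen misses.  Incident validation counts an
algorithm-incident case as correct only when adjudicated incident with a
chart onset date within ±183 days of the claims case date (records lacking
an onset date fall back to the adjudicated class, with that policy
documented on the operation).  Cohen's κ uses the large-sample standard
error √(p₀(1−p₀)/(n(1−pₑ)²)); the SMD for more than two groups is the
maximum pairwise value, labeled as such — the source defines no
multi-group SMD.

Display rounding is to whole percent (halves away from zero); full
precision is retained internally and in machine outputs.

## Synthetic data: what it emulates and what it does not

The generator plants per-patient truth: RA patients whose enrollment,
diagnosis pair, and DMARD are constructed so the true index date is known
(the second diagnosis date, by construction); incident ILD with a clean
baseline, the anchors its planted category requires, and optional accrual
noise inside the 183-day window; prevalent ILD with early specific-code
evidence; sarcoidosis and bronchiectasis confusers; and near-miss patients
who violate exactly one rule by one boundary unit (6-day pair, 91-day CT,
no rheumatologist, 1-day coverage gap, a Part C day, baseline
sarcoidosis).  Defaults are the study-like conditions: 500 patients, 80%
RA, ILD incidence 4.1/1000 person-years (the upper end of reported
clinically significant RA-ILD incidence; recovery tests use an inflated
rate of 40 so enough events exist at desk scale), 5% prevalent ILD and 5%
mimics among RA patients, a 2006–2015 data window with the ICD-9→ICD-10
switch honored at 2015-10-01.  Event dates are uniform within feasibility
constraints from a single seeded stream: the simulator values
reproducibility and rule coverage over billing realism.  It does not
emulate claim-line duplication, miscoding, provider networks, transfer
between payers, or code-frequency distributions — so passing recovery
tests demonstrates that the *rules* are implemented correctly, not that
the algorithm achieves any particular PPV on real claims; the real-data
performance figures come from the embedded reference counts instead.
Synthetic adjudications are derived from truth with configurable
disagreement and insufficient-information rates for end-to-end validation
reports.

## Numerical and design choices

* All window arithmetic is whole-day on closed intervals; "n months" of
  coverage is `n·365/12` days (12 months = 365 days), which keeps every
  rule translation-invariant under global date shifts — a property the
  test suite asserts and calendar-month arithmetic would break.
* Coverage continuity is strict (gap tolerance 0 days) and configurable;
  enrollment data carries no sub-day resolution, so a one-day gap breaks
  the window.
* "Between seven and 365 days apart" is inclusive on both ends; among
  valid diagnosis pairs the earliest second date wins (ties: earliest
  first date), making the index as early as the data allows.
* Each diagnosis claim line is one event; no within-stay deduplication is
  attempted (the data model cannot distinguish re-billed lines from
  genuine re-diagnosis).
* Readers are strict by default (any malformed row fails the load) with a
  configurable bad-row tolerance; all tables are UTF-8 CSV with ISO-8601
  dates, and bundles round-trip byte-identically.

## Known limitations

* The default sensitive code set is partial (see above); per-code results
  on other extracts require configuring the local screening set.
* Specialty is a pre-resolved enum on each event; provider-table linkage
  and specialty inference are out of scope.
* Native CMS research-file layouts (MedPAR, carrier line) are not parsed;
  inputs are normalized CSV event tables.
* Negative predictive value and specificity are not computed — they
  require an ILD ascertainment channel independent of diagnosis codes,
  which claims data cannot provide.
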