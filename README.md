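# raild — claims-based detection of interstitial lung disease in RA cohorts

Interstitial lung disease (ILD) is the best-characterized pulmonary
manifestation of rheumatoid arthritis (RA), with reported prevalence of
5–10% in RA and incidence up to 4.1 per 1000 person-years for clinically
significant disease.  Finding RA-ILD cases — and especially *new-onset*
cases — inside administrative claims streams is what makes population-scale
epidemiology, outcome studies, and trial recruitment for RA-ILD feasible,
because chart review does not scale.

`raild` implements a validated claims-phenotyping pipeline for
epidemiologists and health-services researchers working with Medicare-like
claims extracts:

* **RA cohort identification** — ≥2 RA diagnosis claims (ICD-9-CM
  714.0/714.2) 7–365 days apart with ≥1 from a rheumatologist, ≥1 DMARD
  dispensing, ≥12 months of continuous Part A+B (no Part C) coverage; index
  date = the day all three are first met; baseline exclusions for other
  autoimmune disease, malignancy (except non-melanoma skin cancer), HIV,
  and transplantation.
* **ILD case finding** — an ILD diagnosis from a curated code set counts as
  a case through one of four *case-qualifying* configurations:
  `HospitalPrimary` (inpatient, primary position), `HospitalNonPrimary`
  (inpatient, other position), `OutpatientCT` (outpatient diagnosis by a
  pulmonologist/rheumatologist/internist preceded within 90 days by an
  outpatient chest CT or lung biopsy), or `OutpatientHospital` (the same,
  preceded within 90 days by any hospitalization).  The case-qualifying
  event must fall strictly after the RA index date.
* **Incident vs prevalent classification** — a case is *incident* only if
  no specific ILD code, sarcoidosis code, or lung biopsy appears from the
  start of observable data through `min(index + 365 d, case − 183 d)`; the
  final 183 days before the case date are a diagnostic-accrual window whose
  evidence never disqualifies.
* **Validation statistics** — positive predictive value (PPV) with exact
  Clopper–Pearson binomial intervals
  (`lower = Beta(α/2; x, n−x+1)`, `upper = Beta(1−α/2; x+1, n−x)`),
  sensitivity relative to the broad screen, per-code PPV, incident-onset
  validation with a ±6-month tolerance, Cohen's κ, and standardized mean
  differences.
* **Synthetic claims simulation** — seeded Medicare-like event streams with
  planted RA/ILD truth, confusers (sarcoidosis, bronchiectasis noise,
  prevalent disease) and single-rule near-miss variants, so every rule is
  testable without restricted data.

## Worked example

Simulate a 500-patient extract, build the cohort, detect and classify ILD
cases, and validate against truth-derived adjudications:

```sh
raild run --seed 7 --out demo
```

```
INFO raild: wrote 500 patients to demo/bundle
INFO raild: cohort: 400 members
INFO raild: detected 34 cases
INFO raild: end-to-end run complete: demo
```

Of the 500 simulated patients, 400 satisfy the RA cohort rules and 34
trigger the case-finding algorithm.  `demo/cases.csv` holds one row per
detected case:

```
patient_id,case_date,code,code_system,category,anchor_date,incident,seropositive_proxy
P005,2009-04-09,516.34,ICD9CM,OutpatientCT,2009-01-16,prevalent_or_unclear,False
P019,2008-09-23,516.34,ICD9CM,OutpatientCT,2008-09-14,prevalent_or_unclear,False
...
```

and `demo/validation.csv` the PPV report against the synthetic
adjudications (simulated chart review), e.g.:

```
stratum,tp,n,ppv,ci_lo,ci_hi
All cases,25,34,0.735,0.556,0.871
OutpatientCT,18,18,1.000,0.815,1.000
HospitalNonPrimary,2,11,0.182,0.023,0.518
```

Here 25 of 34 algorithm-positive cases were confirmed (PPV 74%, 95% CI
56–87%); OutpatientCT cases are all genuine while HospitalNonPrimary picks
up the planted sarcoidosis mimics — the same qualitative pattern the
algorithm shows on real data.  Individual pieces are available as
`raild simulate`, `raild ra-cohort`, `raild ild-detect`, `raild validate`,
and `raild codesets dump-default` (the editable code registry).

Library use mirrors the CLI:

```python
from raild import (SimulationScenario, generate, default_registry,
                   build_ra_cohort, detect_cohort_cases)

bundle, truth = generate(SimulationScenario(n_patients=500, seed=7))
registry = default_registry()
members = build_ra_cohort(bundle, registry)
cases = detect_cohort_cases(members, bundle, registry)
```

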