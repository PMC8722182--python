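import datetime as dt

import numpy as np
import pytest

from raild import (
    AlgorithmParams,
    CaseCategory,
    CodeSystem,
    IncidentStatus,
    ProcedureKind,
    Setting,
    Specialty,
    classify_incident,
    detect_ild_case,
    qualify_case,
    screen_ild,
    two_code_variant,
)
from raild.ild import clean_window_end, detect_cohort_cases
from raild.ra_cohort import CohortMember

from conftest import bundle, day, dx, drug, proc, span, stay
from oracles import brute_incident, brute_qualifies


def member(pid="p1", index=0):
    return CohortMember(
        patient_id=pid,
        ra_index_date=day(index),
        first_ra_dx_date=day(index - 60),
        second_ra_dx_date=day(index),
        rheum_dx_date=day(index - 60),
        first_dmard_date=day(index - 10),
        coverage_ok_date=day(index),
    )


def ild_dx(pid="p1", on=0, code="515", setting=Setting.OUTPATIENT, position=1,
           specialty=Specialty.PULMONOLOGIST):
    return dx(pid, on, code, CodeSystem.ICD9CM, setting, position, specialty)


class TestScreen:
    def test_no_ild_codes_absent(self, registry):
        hits = screen_ild([dx(on=0, code="714.0")], registry)
        assert hits == {}

    def test_earliest_screen_code_wins(self, registry):
        hits = screen_ild(
            [ild_dx(on=40, code="515"), ild_dx(on=10, code="518.89")], registry
        )
        assert hits["p1"].code == "518.89" and hits["p1"].service_date == day(10)

    def test_sensitive_codes_are_screened(self, registry):
        hits = screen_ild([ild_dx(on=5, code="494.0")], registry)
        assert "p1" in hits


class TestQualifyCase:
    def test_inpatient_primary_and_non_primary(self, params):
        q = qualify_case(ild_dx(setting=Setting.INPATIENT, position=1), [], [], params)
        assert q.category is CaseCategory.HOSPITAL_PRIMARY
        q = qualify_case(ild_dx(setting=Setting.INPATIENT, position=3), [], [], params)
        assert q.category is CaseCategory.HOSPITAL_NON_PRIMARY

    @pytest.mark.parametrize("offset,expected", [(0, True), (30, True), (90, True), (91, False)])
    def test_ct_window_boundary(self, params, offset, expected):
        q = qualify_case(ild_dx(on=100), [proc(on=100 - offset)], [], params)
        assert (q is not None) is expected
        if q:
            assert q.category is CaseCategory.OUTPATIENT_CT

    def test_lung_biopsy_is_a_ct_class_anchor(self, params):
        q = qualify_case(ild_dx(on=100), [proc(on=80, kind=ProcedureKind.LUNG_BIOPSY)], [], params)
        assert q.category is CaseCategory.OUTPATIENT_CT

    def test_inpatient_ct_does_not_anchor_outpatient_dx(self, params):
        q = qualify_case(ild_dx(on=100), [proc(on=80, setting=Setting.INPATIENT)], [], params)
        assert q is None

    def test_hospitalization_anchor_uses_discharge(self, params):
        q = qualify_case(ild_dx(on=100), [], [stay(admit=2, discharge=15)], params)
        assert q is not None
        assert q.category is CaseCategory.OUTPATIENT_HOSPITAL and q.anchor_date == day(15)
        # a stay discharged after the diagnosis does not anchor by discharge,
        # but with the anchor configured to admit, the admit date governs
        p_admit = AlgorithmParams(hospital_anchor="admit")
        late_stay = [stay(admit=20, discharge=120)]
        assert qualify_case(ild_dx(on=100), [], late_stay, params) is None
        assert qualify_case(ild_dx(on=100), [], late_stay, p_admit).anchor_date == day(20)

    def test_non_qualifying_specialty_rejected(self, params):
        q = qualify_case(ild_dx(specialty=Specialty.OTHER, on=100), [proc(on=90)], [], params)
        assert q is None

    def test_ct_preferred_over_hospitalization(self, params):
        q = qualify_case(ild_dx(on=100), [proc(on=50)], [stay(admit=90, discharge=95)], params)
        assert q.category is CaseCategory.OUTPATIENT_CT

    def test_oracle_agreement_random(self, registry, params):
        rng = np.random.default_rng(11)
        for _ in range(150):
            d = ild_dx(
                on=int(rng.integers(50, 300)),
                setting=list(Setting)[int(rng.integers(2))],
                position=int(rng.integers(1, 4)),
                specialty=list(Specialty)[int(rng.integers(5))],
            )
            procs = [
                proc(on=int(rng.integers(0, 300)),
                     kind=list(ProcedureKind)[int(rng.integers(3))],
                     setting=list(Setting)[int(rng.integers(2))])
                for _ in range(int(rng.integers(0, 3)))
            ]
            admit = int(rng.integers(0, 290))
            stays = [stay(admit=admit, discharge=admit + int(rng.integers(0, 10)))
                     for _ in range(int(rng.integers(0, 2)))]
            got = qualify_case(d, procs, stays, params)
            want = brute_qualifies(bundle(procedures=procs, stays=stays), d, params)
            assert (got.category.value if got else None) == want


class TestDetect:
    def _case_bundle(self, extra_dx=(), extra_proc=(), extra_stay=(), start=-1460):
        return bundle(
            diagnoses=[ild_dx(on=500, setting=Setting.INPATIENT, position=1), *extra_dx],
            procedures=list(extra_proc),
            stays=list(extra_stay),
            start=start,
        )

    def test_simple_inpatient_case(self, registry, params):
        case = detect_ild_case(member(), self._case_bundle(), registry, params)
        assert case.case_date == day(500)
        assert case.qualification.category is CaseCategory.HOSPITAL_PRIMARY
        assert case.qualifying_code == "515"
        assert case.incident is IncidentStatus.INCIDENT

    def test_pre_index_diagnosis_is_not_a_case(self, registry, params):
        b = bundle(diagnoses=[ild_dx(on=-50, setting=Setting.INPATIENT)])
        assert detect_ild_case(member(), b, registry, params) is None

    def test_case_on_index_date_is_not_a_case(self, registry, params):
        b = bundle(diagnoses=[ild_dx(on=0, setting=Setting.INPATIENT)])
        assert detect_ild_case(member(index=0), b, registry, params) is None

    def test_sensitive_code_never_a_case(self, registry, params):
        b = bundle(diagnoses=[ild_dx(on=500, code="518.89", setting=Setting.INPATIENT)])
        assert detect_ild_case(member(), b, registry, params) is None

    def test_same_day_tie_break_prefers_inpatient(self, registry, params):
        b = bundle(
            diagnoses=[
                ild_dx(on=500, setting=Setting.INPATIENT, position=2),
                ild_dx(on=500, code="516.8"),
            ],
            procedures=[proc(on=470)],
        )
        case = detect_ild_case(member(), b, registry, params)
        assert case.qualification.category is CaseCategory.HOSPITAL_NON_PRIMARY

    def test_seropositive_proxy_flag(self, registry, params):
        b = self._case_bundle(extra_dx=[dx(on=100, code="M05.79", system=CodeSystem.ICD10CM)])
        case = detect_ild_case(member(), b, registry, params)
        assert case.seropositive_proxy

    def test_home_oxygen_exclusion_flag(self, registry):
        b = self._case_bundle(extra_proc=[proc(on=100, kind=ProcedureKind.HOME_OXYGEN)])
        on = AlgorithmParams(home_oxygen_exclusion=True)
        assert detect_ild_case(member(), b, registry, on) is None
        assert detect_ild_case(member(), b, registry, AlgorithmParams()) is not None


class TestTwoCodeVariant:
    def _outpatient_case(self, registry, params, extra_dx=()):
        b = bundle(
            diagnoses=[ild_dx(on=500), *extra_dx],
            procedures=[proc(on=480)],
        )
        return detect_ild_case(member(), b, registry, params), b

    def test_second_code_within_window(self, registry, params):
        case, b = self._outpatient_case(registry, params, [ild_dx(on=600, code="516.8")])
        assert two_code_variant(case, b.diagnoses, registry, params)

    def test_no_second_code(self, registry, params):
        case, b = self._outpatient_case(registry, params)
        assert not two_code_variant(case, b.diagnoses, registry, params)

    @pytest.mark.parametrize("offset,expected", [(365, True), (366, False)])
    def test_window_inclusive_boundary(self, registry, params, offset, expected):
        case, b = self._outpatient_case(
            registry, params, [ild_dx(on=500 + offset, code="516.8")]
        )
        assert two_code_variant(case, b.diagnoses, registry, params) is expected

    def test_inpatient_case_is_a_contract_violation(self, registry, params):
        b = bundle(diagnoses=[ild_dx(on=500, setting=Setting.INPATIENT)])
        case = detect_ild_case(member(), b, registry, params)
        with pytest.raises(ValueError, match="outpatient"):
            two_code_variant(case, b.diagnoses, registry, params)

    def test_variant_demotes_single_code_outpatient_cases(self, registry):
        strict = AlgorithmParams(two_code_variant=True)
        case, _ = self._outpatient_case(registry, strict)
        assert case is None


class TestClassifyIncident:
    def test_accrual_window_evidence_allowed(self, registry, params):
        # case at index+700; first-ever evidence at case-100 is inside the
        # 183-day accrual window and must not disqualify
        b = bundle(
            diagnoses=[
                ild_dx(on=600, specialty=Specialty.OTHER),
                ild_dx(on=700, setting=Setting.INPATIENT),
            ]
        )
        case = detect_ild_case(member(), b, registry, params)
        assert case.case_date == day(700)
        assert case.incident is IncidentStatus.INCIDENT

    def test_baseline_specific_code_is_prevalent(self, registry, params):
        b = bundle(
            diagnoses=[
                ild_dx(on=-200, specialty=Specialty.OTHER),
                ild_dx(on=700, setting=Setting.INPATIENT),
            ]
        )
        case = detect_ild_case(member(), b, registry, params)
        assert case.incident is IncidentStatus.PREVALENT_OR_UNCLEAR
        assert any("515" in e for e in case.incident_report.disqualifying_events)

    def test_sarcoid_in_post_index_clean_year(self, registry, params):
        # sarcoid at index+100, case at index+800: clean window runs through
        # min(index+365, case-183) = index+365, so the sarcoid disqualifies
        b = bundle(
            diagnoses=[
                dx(on=100, code="135", specialty=Specialty.OTHER),
                ild_dx(on=800, setting=Setting.INPATIENT),
            ]
        )
        case = detect_ild_case(member(), b, registry, params)
        assert case.incident is IncidentStatus.PREVALENT_OR_UNCLEAR

    def test_early_case_clean_window_ends_at_case_minus_183(self, registry, params):
        b = bundle(diagnoses=[ild_dx(on=300, setting=Setting.INPATIENT)])
        case = detect_ild_case(member(), b, registry, params)
        assert case.incident is IncidentStatus.INCIDENT
        assert case.incident_report.clean_window_end == day(300 - 183)

    def test_baseline_lung_biopsy_disqualifies(self, registry, params):
        b = bundle(
            diagnoses=[ild_dx(on=700, setting=Setting.INPATIENT)],
            procedures=[proc(on=-100, kind=ProcedureKind.LUNG_BIOPSY)],
        )
        case = detect_ild_case(member(), b, registry, params)
        assert case.incident is IncidentStatus.PREVALENT_OR_UNCLEAR

    def test_short_baseline_is_unclassifiable(self, registry, params):
        b = bundle(diagnoses=[ild_dx(on=700, setting=Setting.INPATIENT)], start=-100)
        case = detect_ild_case(member(), b, registry, params)
        assert case.incident is IncidentStatus.UNCLASSIFIABLE

    def test_sensitive_codes_in_baseline_do_not_disqualify(self, registry, params):
        b = bundle(
            diagnoses=[
                ild_dx(on=-300, code="518.89", specialty=Specialty.OTHER),
                ild_dx(on=700, setting=Setting.INPATIENT),
            ]
        )
        case = detect_ild_case(member(), b, registry, params)
        assert case.incident is IncidentStatus.INCIDENT

    def test_adding_baseline_specific_event_is_monotone(self, registry, params):
        base = bundle(diagnoses=[ild_dx(on=700, setting=Setting.INPATIENT)])
        case = detect_ild_case(member(), base, registry, params)
        assert case.incident is IncidentStatus.INCIDENT
        worse = bundle(
            diagnoses=list(base.diagnoses) + [ild_dx(on=-50, specialty=Specialty.OTHER)]
        )
        case2 = detect_ild_case(member(), worse, registry, params)
        assert case2.case_date == case.case_date
        assert case2.incident is IncidentStatus.PREVALENT_OR_UNCLEAR

    def test_translation_invariance(self, registry, params):
        b = bundle(
            diagnoses=[
                dx(on=100, code="135", specialty=Specialty.OTHER),
                ild_dx(on=800, setting=Setting.INPATIENT),
            ]
        )
        base_case = detect_ild_case(member(), b, registry, params)
        for k in (-200, 13, 365):
            m = member(index=k)
            shifted_case = detect_ild_case(m, b.shifted(k), registry, params)
            assert shifted_case.case_date == base_case.case_date + dt.timedelta(days=k)
            assert shifted_case.incident is base_case.incident

    def test_oracle_agreement_random(self, registry, params):
        rng = np.random.default_rng(5)
        codes = ["515", "518.89", "135", "516.8", "250.00"]
        for _ in range(120):
            events = [
                ild_dx(
                    on=int(rng.integers(-900, 900)),
                    code=codes[int(rng.integers(len(codes)))],
                    specialty=Specialty.OTHER,
                )
                for _ in range(int(rng.integers(0, 12)))
            ]
            procs = [
                proc(on=int(rng.integers(-900, 900)), kind=list(ProcedureKind)[int(rng.integers(3))])
                for _ in range(int(rng.integers(0, 3)))
            ]
            case_on = int(rng.integers(1, 900))
            b = bundle(
                diagnoses=events + [ild_dx(on=case_on, setting=Setting.INPATIENT)],
                procedures=procs,
            )
            case = detect_ild_case(member(), b, registry, params, classify=False)
            from raild import classify_incident

            report = classify_incident(case, member(), b, registry, params)
            want = brute_incident(b.for_patient("p1"), day(0), case.case_date, registry, params)
            assert report.status.value == want
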