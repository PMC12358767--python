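"""Case identification, control eligibility and matching rules."""

import numpy as np
import pandas as pd
import pytest

import trioscreen as ts
from tests.conftest import make_diagnoses, make_persons, standard_person


def one_person_frame(**kwargs):
    return make_persons([standard_person("P1", **kwargs)])


def test_ade_code_in_position_three_is_not_a_case(outcome):
    persons = one_person_frame()
    diagnoses = make_diagnoses([
        ("P1", "2010-06-01", "OTHER", 1, 1),
        ("P1", "2010-06-01", "ADE", 3, 1),
    ])
    assert ts.identify_cases(persons, diagnoses, outcome) == []


def test_ade_code_in_position_two_is_a_case(outcome):
    persons = one_person_frame()
    diagnoses = make_diagnoses([
        ("P1", "2010-06-01", "OTHER", 1, 1),
        ("P1", "2010-06-01", "ADE", 2, 1),
    ])
    cases = ts.identify_cases(persons, diagnoses, outcome)
    assert [c.person_id for c in cases] == ["P1"]
    assert cases[0].index_date == np.datetime64("2010-06-01")
    assert cases[0].age_at_index == 60


def test_recent_prior_ed_visit_excludes_the_candidate_visit(outcome):
    persons = one_person_frame()
    diagnoses = make_diagnoses([
        ("P1", "2010-02-21", "OTHER", 1, 1),  # 100 days before
        ("P1", "2010-06-01", "ADE", 1, 1),
    ])
    assert ts.identify_cases(persons, diagnoses, outcome) == []


def test_prior_ed_visit_outside_180_days_is_allowed(outcome):
    persons = one_person_frame()
    diagnoses = make_diagnoses([
        ("P1", "2009-06-01", "OTHER", 1, 1),
        ("P1", "2010-06-01", "ADE", 1, 1),
    ])
    assert len(ts.identify_cases(persons, diagnoses, outcome)) == 1


def test_prior_ade_diagnosis_excludes_case(outcome):
    persons = one_person_frame()
    diagnoses = make_diagnoses([
        ("P1", "2008-06-01", "ADE", 1, 0),  # 2 years before, outpatient
        ("P1", "2010-06-01", "ADE", 1, 1),
    ])
    assert ts.identify_cases(persons, diagnoses, outcome) == []


def test_insufficient_enrollment_excludes_case(outcome):
    persons = one_person_frame(start="2010-01-01")
    diagnoses = make_diagnoses([("P1", "2010-06-01", "ADE", 1, 1)])
    assert ts.identify_cases(persons, diagnoses, outcome) == []


def test_earliest_qualifying_visit_is_chosen(outcome):
    persons = one_person_frame()
    diagnoses = make_diagnoses([
        ("P1", "2010-06-01", "ADE", 1, 1),
        ("P1", "2012-06-01", "ADE", 1, 1),
    ])
    cases = ts.identify_cases(persons, diagnoses, outcome)
    assert len(cases) == 1
    assert cases[0].index_date == np.datetime64("2010-06-01")


def test_identify_cases_is_row_order_independent(outcome):
    persons = make_persons([standard_person("P1"), standard_person("P2")])
    diagnoses = make_diagnoses([
        ("P1", "2010-06-01", "ADE", 1, 1),
        ("P1", "2009-01-01", "RF0", 1, 0),
        ("P2", "2011-06-01", "ADE", 2, 1),
    ])
    forward = ts.identify_cases(persons, diagnoses, outcome)
    backward = ts.identify_cases(
        persons.iloc[::-1].reset_index(drop=True),
        diagnoses.iloc[::-1].reset_index(drop=True),
        outcome,
    )
    assert forward == backward


def test_case_persons_are_not_control_candidates(outcome):
    persons = make_persons([standard_person("P1"), standard_person("P2")])
    diagnoses = make_diagnoses([
        ("P1", "2010-06-01", "ADE", 1, 1),
        ("P2", "2010-06-01", "OTHER", 1, 1),
    ])
    pool = ts.eligible_controls(persons, diagnoses, outcome)
    assert [c.person_id for c in pool] == ["P2"]


def test_control_candidate_with_prior_ade_is_removed(outcome):
    persons = one_person_frame()
    diagnoses = make_diagnoses([
        ("P1", "2009-06-10", "ADE", 1, 0),
        ("P1", "2010-06-01", "OTHER", 1, 1),
    ])
    assert ts.eligible_controls(persons, diagnoses, outcome) == []


def test_empty_diagnosis_history_leaves_ed_visitors_eligible(outcome):
    persons = make_persons([standard_person("P1"), standard_person("P2")])
    diagnoses = make_diagnoses([
        ("P1", "2010-06-01", "OTHER", 1, 1),
        ("P2", "2010-07-01", "OTHER", 1, 1),
    ])
    pool = ts.eligible_controls(persons, diagnoses, outcome)
    assert sorted(c.person_id for c in pool) == ["P1", "P2"]


def test_missing_columns_raise_schema_error(outcome):
    with pytest.raises(ts.SchemaError):
        ts.identify_cases(pd.DataFrame({"person_id": []}), make_diagnoses([]), outcome)


# ------------------------------------------------------------- risk factors

def test_risk_factors_zero_without_history(outcome):
    diagnoses = make_diagnoses([])
    vec = ts.compute_risk_factors(
        diagnoses, outcome, "P1", np.datetime64("2010-06-01")
    )
    assert vec.tolist() == [0, 0]


def test_risk_factor_before_index_is_counted_once(outcome):
    diagnoses = make_diagnoses([("P1", "2009-01-01", "RF1", 1, 0)])
    vec = ts.compute_risk_factors(
        diagnoses, outcome, "P1", pd.Timestamp("2010-06-01")
    )
    assert vec.tolist() == [0, 1]


def test_risk_factor_after_index_is_not_counted(outcome):
    diagnoses = make_diagnoses([("P1", "2011-01-01", "RF0", 1, 0)])
    vec = ts.compute_risk_factors(
        diagnoses, outcome, "P1", pd.Timestamp("2010-06-01")
    )
    assert vec.tolist() == [0, 0]


# ----------------------------------------------------------------- matching

def case_record(pid, index="2010-06-01", age=60, gender="F", race="White", rf=(0, 0)):
    return ts.CaseRecord(
        person_id=pid,
        index_date=np.datetime64(index),
        age_at_index=age,
        gender=gender,
        race=race,
        risk_factors=tuple(rf),
    )


def test_age_beyond_caliper_is_ineligible():
    case = case_record("C1", age=60)
    cand = case_record("K1", age=63)
    pairs, unmatched = ts.match_controls([case], [cand])
    assert pairs == [] and [c.person_id for c in unmatched] == ["C1"]


def test_month_beyond_caliper_is_ineligible():
    case = case_record("C1", index="2010-06-15")
    cand = case_record("K1", index="2010-09-01")  # 3 calendar months later
    pairs, _ = ts.match_controls([case], [cand])
    assert pairs == []


def test_month_caliper_ignores_day_of_month():
    case = case_record("C1", index="2010-06-30")
    cand = case_record("K1", index="2010-08-01")  # 2 calendar months apart
    pairs, _ = ts.match_controls([case], [cand])
    assert len(pairs) == 1


def test_identical_covariates_same_month_match():
    pairs, unmatched = ts.match_controls(
        [case_record("C1")], [case_record("K1")]
    )
    assert len(pairs) == 1 and unmatched == []
    assert pairs[0].match_deltas == (0, 0)


def test_exact_covariates_must_agree():
    case = case_record("C1", gender="F")
    for cand in (
        case_record("K1", gender="M"),
        case_record("K2", race="Black"),
        case_record("K3", rf=(1, 0)),
    ):
        pairs, _ = ts.match_controls([case], [cand])
        assert pairs == []


def test_two_cases_one_candidate_yields_one_pair_one_unmatched():
    cases = [case_record("C1"), case_record("C2", index="2010-06-02")]
    cand = [case_record("K1")]
    pairs, unmatched = ts.match_controls(cases, cand)
    assert len(pairs) == 1 and len(unmatched) == 1
    # earliest index date is served first
    assert pairs[0].case.person_id == "C1"
    assert unmatched[0].person_id == "C2"


def test_nearest_candidate_wins_by_age_then_month():
    case = case_record("C1", age=60, index="2010-06-01")
    far = case_record("K1", age=62, index="2010-06-01")
    near = case_record("K2", age=60, index="2010-08-01")
    pairs, _ = ts.match_controls([case], [far, near])
    assert pairs[0].control.person_id == "K2"


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_matched_pairs_satisfy_all_invariants_on_random_cohorts(seed, outcome):
    persons, diagnoses, _ = ts.generate_population(
        ts.SimConfig(n_persons=800, n_drugs=3, seed=seed, stratum_sd=0.3)
    )
    cases = ts.identify_cases(persons, diagnoses, outcome)
    pool = ts.eligible_controls(persons, diagnoses, outcome)
    pairs, unmatched = ts.match_controls(cases, pool)
    assert len(pairs) + len(unmatched) == len(cases)
    controls_used = [p.control.person_id for p in pairs]
    assert len(controls_used) == len(set(controls_used))  # no reuse
    case_ids = {c.person_id for c in cases}
    for pair in pairs:
        assert pair.control.person_id not in case_ids
        assert abs(pair.case.age_at_index - pair.control.age_at_index) <= 2
        m_case = pair.case.index_date.astype("datetime64[M]").astype(int)
        m_ctrl = pair.control.index_date.astype("datetime64[M]").astype(int)
        assert abs(m_case - m_ctrl) <= 2
        assert pair.case.gender == pair.control.gender
        assert pair.case.race == pair.control.race
        assert pair.case.risk_factors == pair.control.risk_factors
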