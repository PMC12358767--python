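"""Case identification, control eligibility and 1:1 matching.

A *case* is a person's earliest emergency-department (ED) visit carrying
an adverse-event diagnosis code in position 1 or 2, subject to three
inclusion rules applied to the visit:

* more than 365 days of enrollment before the visit date,
* no other ED visit in the 180 days before it,
* the visit falls in the study window (2008-2021 by default),

and one exclusion: any adverse-event diagnosis before the visit removes
the person.  Controls are persons with a qualifying ED visit that does
NOT carry the adverse-event code in positions 1-2 and who have no prior
adverse-event diagnosis at all; case persons never enter the control
pool.

Matching is 1:1 without replacement: exact on gender, race and the
binary risk-factor vector; calipers of +/-2 years on age and +/-2
calendar months on the index year-month.  Cases are processed in
ascending index-date order (ties by person id) and greedily take the
eligible candidate minimising (|age difference|, |month difference|,
person id).  Unmatched cases are reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

PERSON_COLUMNS = ["person_id", "gender", "race", "birth_year", "enroll_start", "enroll_end"]
DIAGNOSIS_COLUMNS = ["person_id", "date", "code", "position", "ed_flag"]

DEFAULT_STUDY_WINDOW = (np.datetime64("2008-01-01"), np.datetime64("2021-12-31"))
MIN_ENROLL_DAYS = 365
ED_WASHOUT_DAYS = 180
AGE_CALIPER = 2
MONTH_CALIPER = 2


@dataclass(frozen=True)
class OutcomeDefinition:
    """One adverse-event outcome: its diagnosis codes and risk-factor map."""

    ade_name: str
    ade_codes: frozenset
    risk_factor_map: dict
    risk_factor_labels: tuple

    def __init__(self, ade_name, ade_codes, risk_factor_map, risk_factor_labels=None):
        codes = frozenset(ade_codes)
        if not codes:
            raise SchemaError("ade_codes must be non-empty")
        if risk_factor_labels is None:
            risk_factor_labels = tuple(sorted(set(risk_factor_map.values())))
        else:
            risk_factor_labels = tuple(risk_factor_labels)
        if len(set(risk_factor_labels)) != len(risk_factor_labels):
            raise SchemaError("risk_factor_labels must be unique")
        object.__setattr__(self, "ade_name", ade_name)
        object.__setattr__(self, "ade_codes", codes)
        object.__setattr__(self, "risk_factor_map", dict(risk_factor_map))
        object.__setattr__(self, "risk_factor_labels", risk_factor_labels)


@dataclass
class CaseRecord:
    """A case (or control candidate) anchored at an index ED-visit date."""

    person_id: str
    index_date: np.datetime64
    age_at_index: int
    gender: str
    race: str
    risk_factors: tuple


@dataclass
class MatchedPair:
    pair_id: int
    case: CaseRecord
    control: CaseRecord
    match_deltas: tuple  # (age difference in years, index-month difference)


def _require_columns(frame: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns: {missing}")


def _as_dates(series: pd.Series) -> pd.Series:
    if np.issubdtype(series.dtype, np.datetime64):
        return series
    return pd.to_datetime(series)


def _age_years(index_date: np.datetime64, birth_year: int) -> int:
    birth = np.datetime64(f"{int(birth_year)}-01-01")
    days = (index_date - birth).astype("timedelta64[D]").astype(int)
    return int(np.floor(days / 365.25))


def _month_index(date: np.datetime64) -> int:
    return date.astype("datetime64[M]").astype(int)


def _qualifying_ed_visits(persons, diagnoses, study_window):
    """Per person, ED-visit dates passing enrollment/washout/window rules."""
    ed = diagnoses[diagnoses["ed_flag"] == 1][["person_id", "date"]].drop_duplicates()
    ed = ed.merge(
        persons[["person_id", "enroll_start", "enroll_end"]], on="person_id", how="inner"
    )
    days_enrolled = (ed["date"] - ed["enroll_start"]).dt.days
    keep = (
        (days_enrolled > MIN_ENROLL_DAYS)
        & (ed["date"] <= ed["enroll_end"])
        & (ed["date"] >= study_window[0])
        & (ed["date"] <= study_window[1])
    )
    ed = ed[keep].copy()
    # washout: no other ED visit within the 180 days before this one
    all_ed = diagnoses[diagnoses["ed_flag"] == 1][["person_id", "date"]].drop_duplicates()
    merged = ed.merge(all_ed, on="person_id", suffixes=("", "_other"))
    gap = (merged["date"] - merged["date_other"]).dt.days
    bad = merged[(gap > 0) & (gap <= ED_WASHOUT_DAYS)][["person_id", "date"]]
    bad_keys = set(zip(bad["person_id"], bad["date"]))
    mask = np.array(
        [(p, d) not in bad_keys for p, d in zip(ed["person_id"], ed["date"])],
        dtype=bool,
    )
    return ed.loc[mask, ["person_id", "date"]]


def _ade_at_visit(diagnoses, outcome):
    """(person, date) keys with an outcome code in diagnosis position 1-2."""
    hit = diagnoses[
        diagnoses["code"].isin(outcome.ade_codes) & diagnoses["position"].isin([1, 2])
    ]
    return hit[["person_id", "date"]].drop_duplicates()


def compute_risk_factors(diagnoses, outcome, person_id, index_date) -> np.ndarray:
    """Binary risk-factor vector from all diagnoses strictly before index."""
    rows = diagnoses[
        (diagnoses["person_id"] == person_id) & (diagnoses["date"] < index_date)
    ]
    labels = {
        outcome.risk_factor_map[c]
        for c in rows["code"]
        if c in outcome.risk_factor_map
    }
    return np.array(
        [1 if lab in labels else 0 for lab in outcome.risk_factor_labels], dtype=int
    )


def _risk_factor_table(diagnoses, outcome, index_lookup):
    """Vectorised risk factors for many (person, index_date) anchors."""
    mapped = diagnoses[diagnoses["code"].isin(outcome.risk_factor_map)].copy()
    mapped["factor"] = mapped["code"].map(outcome.risk_factor_map)
    merged = mapped.merge(index_lookup, on="person_id")
    merged = merged[merged["date"] < merged["index_date"]]
    out = {}
    labels = outcome.risk_factor_labels
    got = merged.groupby("person_id")["factor"].agg(set)
    for pid, idx in zip(index_lookup["person_id"], index_lookup["index_date"]):
        facts = got.get(pid, set())
        out[pid] = tuple(1 if lab in facts else 0 for lab in labels)
    return out


def _build_records(persons, diagnoses, outcome, anchors):
    """Turn (person_id, index_date) anchors into CaseRecord objects."""
    pmap = persons.set_index("person_id")
    lookup = anchors.rename(columns={"date": "index_date"})[["person_id", "index_date"]]
    rf = _risk_factor_table(diagnoses, outcome, lookup)
    records = []
    for pid, idate in zip(lookup["person_id"], lookup["index_date"]):
        row = pmap.loc[pid]
        idate64 = np.datetime64(idate, "D")
        records.append(
            CaseRecord(
                person_id=pid,
                index_date=idate64,
                age_at_index=_age_years(idate64, row["birth_year"]),
                gender=row["gender"],
                race=row["race"],
                risk_factors=rf[pid],
            )
        )
    records.sort(key=lambda r: (r.index_date, r.person_id))
    return records


def identify_cases(persons, diagnoses, outcome: OutcomeDefinition,
                   study_window=DEFAULT_STUDY_WINDOW) -> list[CaseRecord]:
    """Earliest qualifying adverse-event ED visit per person.

    Applies the enrollment, ED-washout and study-window inclusion rules
    and the prior-outcome exclusion; at most one case per person.
    """
    _require_columns(persons, PERSON_COLUMNS, "persons")
    _require_columns(diagnoses, DIAGNOSIS_COLUMNS, "diagnoses")
    persons = persons.copy()
    diagnoses = diagnoses.copy()
    persons["enroll_start"] = _as_dates(persons["enroll_start"])
    persons["enroll_end"] = _as_dates(persons["enroll_end"])
    diagnoses["date"] = _as_dates(diagnoses["date"])

    qualifying = _qualifying_ed_visits(persons, diagnoses, study_window)
    ade_visits = _ade_at_visit(diagnoses, outcome)
    candidates = qualifying.merge(ade_visits, on=["person_id", "date"])
    # earliest qualifying adverse-event visit per person
    candidates = candidates.sort_values(["person_id", "date"]).groupby(
        "person_id", as_index=False
    ).first()
    # prior-outcome exclusion: any outcome code strictly before index
    prior = diagnoses[diagnoses["code"].isin(outcome.ade_codes)][["person_id", "date"]]
    merged = candidates.merge(prior, on="person_id", suffixes=("", "_prior"))
    excluded = set(
        merged[merged["date_prior"] < merged["date"]]["person_id"]
    )
    candidates = candidates[~candidates["person_id"].isin(excluded)]
    return _build_records(persons, diagnoses, outcome, candidates)


def eligible_controls(persons, diagnoses, outcome: OutcomeDefinition,
                      study_window=DEFAULT_STUDY_WINDOW) -> list[CaseRecord]:
    """Control candidate pool with one index ED visit per person.

    A candidate's visit passes the same enrollment/washout/window rules,
    carries no outcome code in positions 1-2 at the visit, and the person
    has no outcome diagnosis before the visit.  Case persons are removed.
    """
    _require_columns(persons, PERSON_COLUMNS, "persons")
    _require_columns(diagnoses, DIAGNOSIS_COLUMNS, "diagnoses")
    persons = persons.copy()
    diagnoses = diagnoses.copy()
    persons["enroll_start"] = _as_dates(persons["enroll_start"])
    persons["enroll_end"] = _as_dates(persons["enroll_end"])
    diagnoses["date"] = _as_dates(diagnoses["date"])

    case_persons = {c.person_id for c in identify_cases(persons, diagnoses, outcome, study_window)}
    qualifying = _qualifying_ed_visits(persons, diagnoses, study_window)
    ade_visits = _ade_at_visit(diagnoses, outcome)
    ade_keys = set(zip(ade_visits["person_id"], ade_visits["date"]))
    mask = np.array(
        [(p, d) not in ade_keys
         for p, d in zip(qualifying["person_id"], qualifying["date"])],
        dtype=bool,
    )
    pool = qualifying.loc[mask]
    pool = pool[~pool["person_id"].isin(case_persons)]
    # earliest qualifying non-outcome visit per person
    pool = pool.sort_values(["person_id", "date"]).groupby(
        "person_id", as_index=False
    ).first()
    # no outcome diagnosis before (or at) the candidate index date
    prior = diagnoses[diagnoses["code"].isin(outcome.ade_codes)][["person_id", "date"]]
    merged = pool.merge(prior, on="person_id", suffixes=("", "_prior"))
    excluded = set(merged[merged["date_prior"] <= merged["date"]]["person_id"])
    pool = pool[~pool["person_id"].isin(excluded)]
    return _build_records(persons, diagnoses, outcome, pool)


def match_controls(cases, candidates) -> tuple[list[MatchedPair], list[CaseRecord]]:
    """Greedy 1:1 matching without replacement.

    Returns (pairs, unmatched_cases).  Determinism: cases in ascending
    (index_date, person_id); best candidate by (|age diff|, |month diff|,
    person_id).
    """
    by_cell: dict = {}
    for cand in candidates:
        key = (cand.gender, cand.race, tuple(cand.risk_factors))
        by_cell.setdefault(key, []).append(cand)
    for cell in by_cell.values():
        cell.sort(key=lambda c: c.person_id)
    used: set = set()
    pairs: list[MatchedPair] = []
    unmatched: list[CaseRecord] = []
    ordered = sorted(cases, key=lambda c: (c.index_date, c.person_id))
    for case in ordered:
        key = (case.gender, case.race, tuple(case.risk_factors))
        best = None
        best_score = None
        case_month = _month_index(case.index_date)
        for cand in by_cell.get(key, ()):
            if cand.person_id in used or cand.person_id == case.person_id:
                continue
            d_age = abs(cand.age_at_index - case.age_at_index)
            if d_age > AGE_CALIPER:
                continue
            d_month = abs(_month_index(cand.index_date) - case_month)
            if d_month > MONTH_CALIPER:
                continue
            score = (d_age, d_month, cand.person_id)
            if best_score is None or score < best_score:
                best, best_score = cand, score
        if best is None:
            unmatched.append(case)
        else:
            used.add(best.person_id)
            pairs.append(
                MatchedPair(
                    pair_id=len(pairs),
                    case=case,
                    control=best,
                    match_deltas=(best_score[0], best_score[1]),
                )
            )
    return pairs, unmatched


def pairs_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    """Long table with one row per pair member (role in {case, control})."""
    rows = []
    for pair in pairs:
        for role, rec in (("case", pair.case), ("control", pair.control)):
            rows.append(
                {
                    "pair_id": pair.pair_id,
                    "role": role,
                    "person_id": rec.person_id,
                    "index_date": pd.Timestamp(rec.index_date),
                    "age_at_index": rec.age_at_index,
                    "gender": rec.gender,
                    "race": rec.race,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pair_id", "role", "person_id", "index_date", "age_at_index", "gender", "race"],
    )
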