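import pandas as pd
import pytest

from trioscreen import OutcomeDefinition


@pytest.fixture
def outcome():
    return OutcomeDefinition(
        ade_name="test_ade",
        ade_codes={"ADE"},
        risk_factor_map={"RF0": "factor_0", "RF1": "factor_1"},
    )


def make_persons(rows):
    """rows: list of (person_id, gender, race, birth_year, start, end)."""
    frame = pd.DataFrame(
        rows,
        columns=["person_id", "gender", "race", "birth_year", "enroll_start", "enroll_end"],
    )
    frame["enroll_start"] = pd.to_datetime(frame["enroll_start"])
    frame["enroll_end"] = pd.to_datetime(frame["enroll_end"])
    return frame


def make_diagnoses(rows):
    """rows: list of (person_id, date, code, position, ed_flag)."""
    frame = pd.DataFrame(
        rows, columns=["person_id", "date", "code", "position", "ed_flag"]
    )
    frame["date"] = pd.to_datetime(frame["date"])
    return frame


def make_claims(rows):
    """rows: (person_id, fill_date, ingredient, unit, dose, qty, days)."""
    frame = pd.DataFrame(
        rows,
        columns=[
            "person_id", "fill_date", "ingredient", "unit",
            "dose_per_unit", "quantity", "days_supply",
        ],
    )
    frame["fill_date"] = pd.to_datetime(frame["fill_date"])
    return frame


def standard_person(pid, gender="F", race="White", birth_year=1950,
                    start="2008-01-01", end="2016-01-01"):
    return (pid, gender, race, birth_year, start, end)
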