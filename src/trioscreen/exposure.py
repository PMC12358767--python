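"""Average-daily-dose computation and ternary dose coding.

For each drug ingredient-unit combination, the average daily dose (ADS)
over the exposure window is

    ADS = sum(dose_per_unit * quantity) / sum(days_supply)

pooled over all fills dated in ``[index - window, index)``; the default
window is the 30 days before the index date.  Dose codes are 0 for no
exposure (ADS = 0), 1 for low (0 < ADS <= median ADS among exposed
cases) and 2 for high (ADS > that median).  Thresholds are computed from
cases only, so control exposures never move them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

CLAIM_COLUMNS = [
    "person_id", "fill_date", "ingredient", "unit",
    "dose_per_unit", "quantity", "days_supply",
]

DEFAULT_WINDOW_DAYS = 30
DEFAULT_TOP_K = 200


@dataclass(frozen=True)
class DoseThreshold:
    """Median ADS among exposed cases for one drug ingredient-unit."""

    ingredient: str
    unit: str
    median_ads: float
    n_exposed_cases: int

    def __post_init__(self):
        if self.median_ads <= 0:
            raise DataError("median_ads must be positive")


def _require_claims(claims: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLAIM_COLUMNS if c not in claims.columns]
    if missing:
        raise SchemaError(f"claims table is missing columns: {missing}")
    claims = claims.copy()
    if not np.issubdtype(claims["fill_date"].dtype, np.datetime64):
        claims["fill_date"] = pd.to_datetime(claims["fill_date"])
    return claims


def _window_fills(claims, index_lookup, window_days):
    """In-window fills joined to their anchor rows; bad rows rejected."""
    merged = claims.merge(index_lookup, on="person_id", how="inner")
    delta = (merged["index_date"] - merged["fill_date"]).dt.days
    merged = merged[(delta >= 1) & (delta <= window_days)]
    bad = merged["days_supply"] <= 0
    if bad.any():
        logger.warning(
            "rejected %d in-window fill(s) with non-positive days_supply",
            int(bad.sum()),
        )
        merged = merged[~bad]
    return merged


def ads_table(claims, index_lookup, window_days: int = DEFAULT_WINDOW_DAYS) -> pd.DataFrame:
    """Pooled ADS per anchor row and drug-unit.

    ``index_lookup`` carries one row per anchor (columns ``person_id``,
    ``index_date`` plus any keys to carry through, e.g. ``pair_id`` and
    ``role``).  Returns a long table with those keys plus ``ingredient``,
    ``unit`` and ``ads``; drug-units without an in-window fill are absent
    (implicitly ADS 0).
    """
    if window_days <= 0:
        raise DataError("window_days must be positive")
    claims = _require_claims(claims)
    lookup = index_lookup.copy()
    if not np.issubdtype(lookup["index_date"].dtype, np.datetime64):
        lookup["index_date"] = pd.to_datetime(lookup["index_date"])
    merged = _window_fills(claims, lookup, window_days)
    if merged.empty:
        keys = [c for c in lookup.columns if c != "index_date"]
        return pd.DataFrame(columns=keys + ["ingredient", "unit", "ads"])
    merged["dose_mass"] = merged["dose_per_unit"] * merged["quantity"]
    keys = [c for c in lookup.columns if c != "index_date"]
    grouped = (
        merged.groupby(keys + ["ingredient", "unit"], as_index=False)
        .agg(dose_mass=("dose_mass", "sum"), days=("days_supply", "sum"))
    )
    grouped["ads"] = grouped["dose_mass"] / grouped["days"]
    return grouped.drop(columns=["dose_mass", "days"])


def compute_ads(claims, person_id, index_date,
                window_days: int = DEFAULT_WINDOW_DAYS) -> dict:
    """ADS per drug-unit for one person at one index date.

    Returns a mapping ``(ingredient, unit) -> ads``; absent drug-units
    have ADS 0.
    """
    lookup = pd.DataFrame(
        {"person_id": [person_id], "index_date": [pd.Timestamp(index_date)]}
    )
    table = ads_table(claims, lookup, window_days)
    return {
        (row.ingredient, row.unit): float(row.ads) for row in table.itertuples()
    }


def select_top_drug_units(case_ads_table: pd.DataFrame,
                          k: int = DEFAULT_TOP_K) -> list[tuple[str, str]]:
    """The k drug-units with the most exposed cases; ties lexicographic.

    ``case_ads_table`` is the :func:`ads_table` output restricted to case
    rows (one row per case and drug-unit, ADS > 0).
    """
    if k < 1:
        raise DataError("k must be >= 1")
    exposed = case_ads_table[case_ads_table["ads"] > 0]
    counts = (
        exposed.groupby(["ingredient", "unit"])
        .size()
        .reset_index(name="n")
        .sort_values(["n", "ingredient", "unit"], ascending=[False, True, True])
    )
    return [tuple(t) for t in counts.head(k)[["ingredient", "unit"]].itertuples(index=False)]


def compute_thresholds(case_ads_table: pd.DataFrame,
                       drug_units: list[tuple[str, str]]) -> list[DoseThreshold]:
    """Median ADS among exposed cases per drug-unit.

    The sample median uses the mean of the two middle order statistics
    for even counts.  Drug-units with no exposed case are excluded with a
    warning.
    """
    exposed = case_ads_table[case_ads_table["ads"] > 0]
    grouped = exposed.groupby(["ingredient", "unit"])["ads"]
    medians = grouped.median()
    counts = grouped.size()
    thresholds = []
    for unit_key in drug_units:
        if unit_key in medians.index:
            thresholds.append(
                DoseThreshold(
                    ingredient=unit_key[0],
                    unit=unit_key[1],
                    median_ads=float(medians.loc[unit_key]),
                    n_exposed_cases=int(counts.loc[unit_key]),
                )
            )
        else:
            logger.warning("drug-unit %s has no exposed case; threshold skipped", unit_key)
    return thresholds


def code_dose(ads: float, threshold: DoseThreshold) -> int:
    """Ternary dose code: 0 if ADS=0, 1 if 0<ADS<=median, 2 if ADS>median."""
    if ads < 0:
        raise DataError("ADS must be non-negative")
    if ads == 0:
        return 0
    return 1 if ads <= threshold.median_ads else 2


def column_name(ingredient: str, unit: str) -> str:
    return f"{ingredient}|{unit}"


def build_dose_matrix(ads_long: pd.DataFrame,
                      thresholds: list[DoseThreshold],
                      member_index: pd.DataFrame) -> pd.DataFrame:
    """Wide 0/1/2 dose-code matrix, one row per pair member.

    ``member_index`` carries the (pair_id, role) rows the matrix must
    cover (members with no in-window fill get all-zero codes);
    ``ads_long`` is the :func:`ads_table` output keyed by pair_id/role.
    """
    matrix = member_index[["pair_id", "role"]].drop_duplicates().sort_values(
        ["pair_id", "role"]
    ).reset_index(drop=True)
    for thr in thresholds:
        col = column_name(thr.ingredient, thr.unit)
        rows = ads_long[
            (ads_long["ingredient"] == thr.ingredient) & (ads_long["unit"] == thr.unit)
        ][["pair_id", "role", "ads"]]
        merged = matrix.merge(rows, on=["pair_id", "role"], how="left")
        ads = merged["ads"].fillna(0.0).to_numpy()
        codes = np.zeros(len(ads), dtype=np.int64)
        codes[(ads > 0) & (ads <= thr.median_ads)] = 1
        codes[ads > thr.median_ads] = 2
        matrix[col] = codes
    return matrix
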