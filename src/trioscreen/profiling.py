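"""Dose-configuration odds-ratio profiles and dose-reduction tests.

For a fitted triplet, the profile holds the odds ratio (with 95% CI) of
every configuration in {0,1,2}^3 relative to (0,0,0), plus ten one-sided
z-tests comparing the highest dose level (2,2,2) against the reduced
configurations

    221 212 122   — dose reduction for one drug
    211 121 112   — dose reduction for two drugs
    111           — dose reduction for three drugs
    220 202 022   — exposure reduction (discontinuation) for one drug

Each contrast vector is the design-row difference
row(2,2,2) - row(config); e.g. 221 gives (0,0,1,0,2,2,4) and 022 gives
(2,0,0,4,4,0,8).  A reduction is significant at p < 0.05 (one-sided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clrm import TripletFit, design_row, log_or_at, wald_contrast
from .errors import DataError

#: Reduced configurations tested against (2,2,2), in reporting order.
REDUCTION_LABELS = ("221", "212", "122", "211", "121", "112", "111", "220", "202", "022")

#: Strata for the median-odds-ratio summary.
MEDIAN_STRATA = (
    ("highest_dose", ("222",)),
    ("one_drug_lower", ("122", "212", "221")),
    ("two_drugs_lower", ("112", "121", "211")),
    ("three_drugs_lower", ("111",)),
)

Z95 = 1.959963984540054


def _config_of(label: str) -> tuple[int, int, int]:
    return tuple(int(ch) for ch in label)


def reduction_contrast(label: str) -> np.ndarray:
    """Contrast vector for ``(2,2,2)`` minus the labelled configuration."""
    if label not in REDUCTION_LABELS:
        raise DataError(f"unknown reduction label {label!r}")
    return design_row(2, 2, 2) - design_row(*_config_of(label))


@dataclass
class OrEstimate:
    or_: float
    ci_low: float
    ci_high: float


@dataclass
class DoseProfile:
    """Complete odds-ratio grid and reduction tests for one triplet."""

    triplet: tuple
    or_grid: dict  # label "abc" -> OrEstimate
    reduction_tests: dict  # label -> ContrastResult
    percent_reduction: dict  # label -> percentage drop vs OR(2,2,2)
    significant: dict  # label -> bool (one-sided p < 0.05)


@dataclass
class MedianSummary:
    stratum: str
    median_or: float
    n: int


def percent_reduction(or_high: float, or_low: float) -> float:
    """Percentage decrement of the odds ratio: 100 * (1 - low/high)."""
    if or_high <= 0 or or_low <= 0:
        raise DataError("odds ratios must be positive")
    return 100.0 * (1.0 - or_low / or_high)


def build_profile(fit: TripletFit, alpha: float = 0.05) -> DoseProfile:
    """Full 27-configuration profile and the ten reduction z-tests."""
    grid = {}
    for x1 in (0, 1, 2):
        for x2 in (0, 1, 2):
            for x3 in (0, 1, 2):
                est, se = log_or_at(fit, x1, x2, x3)
                grid[f"{x1}{x2}{x3}"] = OrEstimate(
                    or_=float(np.exp(est)),
                    ci_low=float(np.exp(est - Z95 * se)),
                    ci_high=float(np.exp(est + Z95 * se)),
                )
    tests = {}
    pct = {}
    sig = {}
    or_222 = grid["222"].or_
    for label in REDUCTION_LABELS:
        res = wald_contrast(fit, reduction_contrast(label), label=f"222_vs_{label}")
        tests[label] = res
        pct[label] = percent_reduction(or_222, grid[label].or_)
        sig[label] = res.p_one_sided < alpha
    return DoseProfile(
        triplet=fit.triplet,
        or_grid=grid,
        reduction_tests=tests,
        percent_reduction=pct,
        significant=sig,
    )


def summarize_medians(profiles: list, per_signal: bool = False) -> list[MedianSummary]:
    """Median odds ratio per dose stratum across a set of profiles.

    By default, the odds ratios of every configuration in a stratum are
    pooled across profiles before taking the median (each one-drug-lower
    profile contributes three values).  With ``per_signal=True`` each
    profile is first collapsed to its own stratum median and the median
    is taken across profiles.
    """
    out = []
    for stratum, labels in MEDIAN_STRATA:
        if per_signal:
            values = [
                float(np.median([p.or_grid[lab].or_ for lab in labels]))
                for p in profiles
            ]
        else:
            values = [p.or_grid[lab].or_ for p in profiles for lab in labels]
        if values:
            out.append(
                MedianSummary(
                    stratum=stratum,
                    median_or=float(np.median(values)),
                    n=len(values),
                )
            )
    return out


def profiles_frame(profiles: list) -> pd.DataFrame:
    """Flat per-configuration table across profiles (figure-style)."""
    rows = []
    for prof in profiles:
        for label in sorted(prof.or_grid):
            est = prof.or_grid[label]
            row = {
                "drug1": prof.triplet[0],
                "drug2": prof.triplet[1],
                "drug3": prof.triplet[2],
                "config": label,
                "odds_ratio": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
            if label in prof.reduction_tests:
                row["p_reduction"] = prof.reduction_tests[label].p_one_sided
                row["percent_reduction"] = prof.percent_reduction[label]
                row["significant"] = prof.significant[label]
            rows.append(row)
    return pd.DataFrame(rows)


def medians_frame(summaries: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"stratum": s.stratum, "median_or": s.median_or, "n": s.n}
            for s in summaries
        ]
    )
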