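"""Triplet enumeration, the 8-test battery, pooled BH-FDR and signal
selection.

For every eligible drug triplet the conditional logistic fit yields
seven one-sided Wald p-values (one per coefficient, H0: beta_j <= 0) and
one composite p-value for the highest-dose log odds ratio
(2b1+2b2+2b3+4b4+4b5+4b6+8b7 <= 0) — eight p-values per triplet.  All
p-values from all tested triplets enter a single Benjamini-Hochberg
family.  A triplet is flagged as a signal when the composite q-value
clears the FDR level, the odds ratio at dose (2,2,2) clears the
effect-size floor, and every drug shows a risky pattern (positive main
effect or membership in an FDR-significant interaction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clrm import TripletDesign, TripletFit, design_row, fit_clrm, log_or_at, wald_contrast
from .errors import ConfigurationError, FitError, RankDeficiencyError

#: Battery labels in fixed order: the seven coefficients, then the
#: highest-dose composite.
BATTERY_LABELS = (
    "beta1", "beta2", "beta3", "beta4", "beta5", "beta6", "beta7", "composite_222",
)

#: Interaction coefficient indices (0-based) touching each drug position.
_INTERACTIONS_BY_DRUG = ({3, 4, 6}, {3, 5, 6}, {4, 5, 6})


@dataclass
class ScreeningPolicy:
    """Eligibility, multiplicity and effect-size thresholds for a screen."""

    min_case_count: int = 500
    required_drug_set: frozenset = frozenset()
    top_k: int = 200
    fdr_level: float = 0.05
    or_min: float = 1.3
    subgroup_min_age: int | None = None
    strict_or_all_configs: bool = False
    pattern_criterion: bool = True

    def __post_init__(self):
        if self.min_case_count < 1:
            raise ConfigurationError("min_case_count must be >= 1")
        if not 0 < self.fdr_level < 1:
            raise ConfigurationError("fdr_level must be in (0, 1)")
        if self.or_min < 1:
            raise ConfigurationError("or_min must be >= 1")
        self.required_drug_set = frozenset(self.required_drug_set)


@dataclass
class ScreeningResult:
    """Battery outcome for one tested triplet."""

    triplet: tuple
    fit: TripletFit
    p_values: dict
    q_values: dict = field(default_factory=dict)
    or_222: float = float("nan")
    signal: bool = False
    reason_codes: list = field(default_factory=list)


@dataclass
class ScreeningOutcome:
    """A full screen: tested triplets, quarantined triplets, policy."""

    results: list
    quarantined: list  # (triplet, reason) for unconverged/separated fits
    policy: ScreeningPolicy
    n_pooled_tests: int = 0

    @property
    def signals(self) -> list:
        return [r for r in self.results if r.signal]


def enumerate_triplets(dose_matrix: pd.DataFrame, policy: ScreeningPolicy) -> list[tuple]:
    """Unordered drug-unit triplets frequent enough in cases.

    A triplet qualifies when at least ``min_case_count`` cases are
    exposed (code > 0) to all three drug-units and the triplet contains
    at least one drug from ``required_drug_set``.  Output is canonically
    ordered: lexicographic within a triplet and across triplets.
    """
    if not policy.required_drug_set:
        raise ConfigurationError(
            "required_drug_set must be non-empty (outcome-related drug filter)"
        )
    columns = [c for c in dose_matrix.columns if c not in ("pair_id", "role")]
    cases = dose_matrix[dose_matrix["role"] == "case"]
    exposed = cases[columns].to_numpy() > 0
    col_index = {c: j for j, c in enumerate(columns)}
    # prune: a triplet can never beat its least-exposed member
    col_counts = exposed.sum(axis=0)
    viable = [c for c in columns if col_counts[col_index[c]] >= policy.min_case_count]
    required = [c for c in viable if c in policy.required_drug_set]
    out = set()
    for req in required:
        others = [c for c in viable if c != req]
        e_req = exposed[:, col_index[req]]
        for a, b in itertools.combinations(others, 2):
            trip = tuple(sorted((req, a, b)))
            if trip in out:
                continue
            n_co = int(
                (e_req & exposed[:, col_index[a]] & exposed[:, col_index[b]]).sum()
            )
            if n_co >= policy.min_case_count:
                out.add(trip)
    return sorted(out)


def triplet_design(dose_matrix: pd.DataFrame, triplet: tuple) -> TripletDesign:
    """Aligned case/control dose-code design for one triplet."""
    cols = list(triplet)
    ordered = dose_matrix.sort_values(["pair_id", "role"])
    cases = ordered[ordered["role"] == "case"]
    controls = ordered[ordered["role"] == "control"]
    if not np.array_equal(cases["pair_id"].to_numpy(), controls["pair_id"].to_numpy()):
        raise FitError("dose matrix does not pair cases and controls 1:1")
    return TripletDesign.from_codes(
        triplet, cases[cols].to_numpy(), controls[cols].to_numpy()
    )


def run_battery(design: TripletDesign, fit: TripletFit) -> dict:
    """The eight labelled one-sided p-values for one fitted triplet.

    Unconverged or separated fits yield ``{"untested": reason}``; such
    records are excluded from BH pooling.
    """
    if not fit.usable:
        reason = "separation" if fit.separation_flag else "no convergence"
        return {"untested": reason}
    p = {}
    for j in range(7):
        c = np.zeros(7)
        c[j] = 1.0
        p[BATTERY_LABELS[j]] = wald_contrast(fit, c, BATTERY_LABELS[j]).p_one_sided
    composite = design_row(2, 2, 2)
    p["composite_222"] = wald_contrast(fit, composite, "composite_222").p_one_sided
    return p


def apply_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q(i) = min over j >= i of p(j) * m / j on the sorted p-values
    (cumulative minimum from the largest rank), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _or_config_grid(fit: TripletFit):
    grid = {}
    for x1 in (0, 1, 2):
        for x2 in (0, 1, 2):
            for x3 in (0, 1, 2):
                est, _ = log_or_at(fit, x1, x2, x3)
                grid[(x1, x2, x3)] = float(np.exp(est))
    return grid


def select_signals(results: list, policy: ScreeningPolicy) -> list:
    """Apply the signal rule in place; returns the selected results.

    Signal iff (a) composite q < fdr_level, (b) OR at (2,2,2) >= or_min,
    and (c) each drug has a positive main-effect estimate or sits in an
    interaction term with q < fdr_level.  ``reason_codes`` record which
    criterion failed for every non-signal.
    """
    selected = []
    for res in results:
        reasons = []
        q = res.q_values
        if not q:
            res.signal = False
            res.reason_codes = ["untested"]
            continue
        if not q["composite_222"] < policy.fdr_level:
            reasons.append("composite_q_above_fdr")
        if not res.or_222 >= policy.or_min:
            reasons.append("or_222_below_min")
        if policy.strict_or_all_configs and not reasons:
            grid = _or_config_grid(res.fit)
            low = [cfg for cfg, v in grid.items() if cfg != (0, 0, 0) and v < policy.or_min]
            if low:
                reasons.append("or_below_min_at_" + ",".join("".join(map(str, c)) for c in low))
        if policy.pattern_criterion:
            for pos in range(3):
                main_positive = res.fit.beta[pos] > 0
                inter_sig = any(
                    q[BATTERY_LABELS[j]] < policy.fdr_level
                    for j in _INTERACTIONS_BY_DRUG[pos]
                )
                if not (main_positive or inter_sig):
                    reasons.append(f"pattern_drug{pos + 1}")
        res.signal = not reasons
        res.reason_codes = reasons
        if res.signal:
            selected.append(res)
    return selected


def screen(dose_matrix: pd.DataFrame, policy: ScreeningPolicy) -> ScreeningOutcome:
    """Run the full screen on a pair-member dose matrix.

    Enumerates eligible triplets, fits each, pools every tested triplet's
    eight p-values into one BH family, and applies the signal rule.
    Unconverged/separated/degenerate triplets land in the quarantine
    list, never silently dropped.
    """
    triplets = enumerate_triplets(dose_matrix, policy)
    results: list[ScreeningResult] = []
    quarantined: list[tuple] = []
    for trip in triplets:
        design = triplet_design(dose_matrix, trip)
        try:
            fit = fit_clrm(design)
        except RankDeficiencyError as err:
            quarantined.append((trip, f"rank deficiency: {err.aliased_columns}"))
            continue
        except FitError as err:
            quarantined.append((trip, str(err)))
            continue
        p = run_battery(design, fit)
        if "untested" in p:
            quarantined.append((trip, p["untested"]))
            continue
        est, _ = log_or_at(fit, 2, 2, 2)
        results.append(
            ScreeningResult(
                triplet=trip, fit=fit, p_values=p, or_222=float(np.exp(est))
            )
        )
    pooled = np.array(
        [res.p_values[lab] for res in results for lab in BATTERY_LABELS]
    )
    q = apply_bh(pooled)
    for i, res in enumerate(results):
        res.q_values = {
            lab: float(q[i * len(BATTERY_LABELS) + j])
            for j, lab in enumerate(BATTERY_LABELS)
        }
    select_signals(results, policy)
    return ScreeningOutcome(
        results=results,
        quarantined=quarantined,
        policy=policy,
        n_pooled_tests=int(pooled.size),
    )


def subgroup_filter(pairs: pd.DataFrame, min_age: int) -> pd.DataFrame:
    """Retain whole pairs whose case is at least ``min_age`` years old."""
    cases = pairs[(pairs["role"] == "case") & (pairs["age_at_index"] >= min_age)]
    keep = set(cases["pair_id"])
    return pairs[pairs["pair_id"].isin(keep)].reset_index(drop=True)


def results_frame(outcome: ScreeningOutcome) -> pd.DataFrame:
    """Flat table of the screen (one row per tested triplet)."""
    rows = []
    for res in outcome.results:
        row = {
            "drug1": res.triplet[0],
            "drug2": res.triplet[1],
            "drug3": res.triplet[2],
            "n_pairs": res.fit.n_pairs,
            "n_discordant": res.fit.n_discordant,
            "or_222": res.or_222,
            "signal": res.signal,
            "reason_codes": ";".join(res.reason_codes),
        }
        for lab in BATTERY_LABELS:
            row[f"p_{lab}"] = res.p_values[lab]
        for lab in BATTERY_LABELS:
            row[f"q_{lab}"] = res.q_values[lab]
        rows.append(row)
    return pd.DataFrame(rows)
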