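"""Seeded synthetic claims and matched-pair generators.

Two levels of synthetic input are produced:

* :func:`generate_population` emits relational claims-style tables
  (persons, diagnoses, pharmacy claims) to exercise the full pipeline —
  case identification, exclusion rules, matching, dose coding, screening.
* :func:`generate_matched_pairs` draws 1:1 matched pairs directly from
  the exact conditional model: given the two members' dose triples with
  linear predictors eta_a and eta_b, the probability that member A is the
  case is exp(eta_a) / (exp(eta_a) + exp(eta_b)).  This is the sampling
  distribution the conditional logistic fit assumes, so it supports
  estimator-recovery and calibration experiments with no nuisance error.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; sub-generators take spawned child seeds so
outputs are byte-identical across runs with the same config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .clrm import design_matrix
from .errors import ConfigurationError

STUDY_START = np.datetime64("2008-01-01")
STUDY_END = np.datetime64("2021-12-31")

#: Default per-drug dose-level distribution for pair simulation:
#: half of members unexposed, exposed members split evenly low/high
#: (the median split among the exposed, by construction).
DEFAULT_DOSE_LEVEL_PROBS = (0.5, 0.25, 0.25)


@dataclass
class SimConfig:
    """Configuration for the raw claims-table generator.

    ``planted_effects`` is a list of (drug-index triplet, 7-vector of
    log-odds-ratio coefficients on the 0/1/2 dose codes); the coded doses
    enter the person-level outcome model through the usual 7-term design
    row.  ``stratum_sd`` injects a normal random intercept shared by
    persons in the same matching cell, emulating stratum heterogeneity.
    """

    n_persons: int
    n_drugs: int = 6
    drug_exposure_probs: tuple | float = 0.35
    ads_logmean: tuple | float = 3.0
    ads_logsd: tuple | float = 0.6
    planted_effects: list = field(default_factory=list)
    nuisance_main_effects: tuple | float = 0.0
    risk_factor_prevalences: tuple = (0.3, 0.2)
    outcome_prevalence: float = 0.12
    stratum_sd: float = 0.0
    prior_ed_frac: float = 0.03
    prior_ade_frac: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ConfigurationError("n_persons must be positive")
        if self.n_drugs <= 0:
            raise ConfigurationError("n_drugs must be positive")
        for name in ("drug_exposure_probs", "risk_factor_prevalences",
                     "outcome_prevalence", "prior_ed_frac", "prior_ade_frac"):
            vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(vals < 0) or np.any(vals > 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if np.any(np.atleast_1d(np.asarray(self.ads_logsd, dtype=float)) <= 0):
            raise ConfigurationError("ads_logsd must be positive")
        for triplet, beta in self.planted_effects:
            if len(triplet) != 3 or len(set(triplet)) != 3:
                raise ConfigurationError("planted triplet must have 3 distinct drugs")
            if any(not 0 <= d < self.n_drugs for d in triplet):
                raise ConfigurationError("planted drug index out of range")
            if len(beta) != 7:
                raise ConfigurationError("planted beta must have 7 entries")

    def drug_units(self) -> list[tuple[str, str]]:
        """Ingredient-unit identifiers for the simulated drugs."""
        return [(f"drug{i:02d}", "mg") for i in range(self.n_drugs)]


@dataclass
class PairSimConfig:
    """Configuration for direct matched-pair simulation.

    ``beta`` holds the seven log-odds-ratio coefficients; ``dose_level_probs``
    gives the marginal distribution of each member's dose code per drug,
    either one row of three probabilities shared by all drugs or a (3, 3)
    array with one row per drug.
    """

    n_pairs: int
    beta: tuple = (0.0,) * 7
    dose_level_probs: tuple = DEFAULT_DOSE_LEVEL_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ConfigurationError("n_pairs must be >= 1")
        if len(self.beta) != 7:
            raise ConfigurationError("beta must have 7 entries")
        probs = np.atleast_2d(np.asarray(self.dose_level_probs, dtype=float))
        if probs.shape not in ((1, 3), (3, 3)):
            raise ConfigurationError("dose_level_probs must be a 3-vector or 3x3")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0):
            raise ConfigurationError("dose_level_probs rows must sum to 1")

    def prob_matrix(self) -> np.ndarray:
        probs = np.atleast_2d(np.asarray(self.dose_level_probs, dtype=float))
        return np.broadcast_to(probs, (3, 3)).copy()


def _sample_codes(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    """Draw an (n, 3) array of dose codes with per-drug level probabilities."""
    u = rng.random((n, 3))
    cum = probs.cumsum(axis=1)  # (3 drugs, 3 levels)
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int64)


def generate_matched_pairs(config: PairSimConfig) -> pd.DataFrame:
    """Simulate matched pairs from the exact within-pair conditional model.

    Returns a long table with two rows per pair (``member`` is "case" or
    "control") and dose codes ``x1, x2, x3``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    probs = config.prob_matrix()
    beta = np.asarray(config.beta, dtype=float)
    n = config.n_pairs

    codes_a = _sample_codes(rng, n, probs)
    codes_b = _sample_codes(rng, n, probs)
    eta_a = design_matrix(codes_a) @ beta
    eta_b = design_matrix(codes_b) @ beta
    p_a_case = expit(eta_a - eta_b)
    a_is_case = rng.random(n) < p_a_case

    case_codes = np.where(a_is_case[:, None], codes_a, codes_b)
    control_codes = np.where(a_is_case[:, None], codes_b, codes_a)
    pair_ids = np.repeat(np.arange(n), 2)
    member = np.tile(["case", "control"], n)
    codes = np.empty((2 * n, 3), dtype=np.int64)
    codes[0::2] = case_codes
    codes[1::2] = control_codes
    return pd.DataFrame(
        {
            "pair_id": pair_ids,
            "member": member,
            "x1": codes[:, 0],
            "x2": codes[:, 1],
            "x3": codes[:, 2],
        }
    )


def pair_codes(pairs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a pair table into aligned (n, 3) case and control code arrays."""
    wide = pairs.sort_values(["pair_id", "member"])
    cases = wide[wide["member"] == "case"]
    controls = wide[wide["member"] == "control"]
    cols = ["x1", "x2", "x3"]
    return cases[cols].to_numpy(), controls[cols].to_numpy()


def generate_population(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate persons, diagnoses and pharmacy-claims tables.

    Every person carries one emergency-department (ED) visit inside their
    enrollment interval; the adverse-event outcome at that visit follows a
    logistic model on the coded doses with the configured planted triplet
    effects, nuisance main effects and matching-cell random intercept.
    Small fractions of persons receive a prior ED visit within 180 days or
    a prior adverse-event diagnosis so the cohort exclusion rules are
    exercised.
    """
    ss = np.random.SeedSequence(config.seed)
    (r_person, r_expo, r_outcome, r_claims, r_history) = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n = config.n_persons
    d = config.n_drugs

    person_id = np.array([f"P{i:06d}" for i in range(n)])
    gender = np.where(r_person.random(n) < 0.5, "F", "M")
    race = np.where(r_person.random(n) < 0.7, "White", "Black")
    birth_year = r_person.integers(1940, 1976, size=n)
    enroll_start = STUDY_START + r_person.integers(0, 4 * 365, size=n).astype(
        "timedelta64[D]"
    )
    enroll_len = r_person.integers(4 * 365, 8 * 365, size=n)
    enroll_end = enroll_start + enroll_len.astype("timedelta64[D]")
    index_offset = 366 + (
        r_person.random(n) * (enroll_len - 367)
    ).astype(np.int64)
    index_date = enroll_start + index_offset.astype("timedelta64[D]")

    prevalences = np.atleast_1d(np.asarray(config.risk_factor_prevalences, dtype=float))
    n_rf = prevalences.shape[0]
    rf = (r_person.random((n, n_rf)) < prevalences[None, :]).astype(np.int64)

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "gender": gender,
            "race": race,
            "birth_year": birth_year,
            "enroll_start": enroll_start,
            "enroll_end": enroll_end,
        }
    )

    # --- drug exposure and true average daily dose -----------------------
    expo_probs = np.broadcast_to(
        np.atleast_1d(np.asarray(config.drug_exposure_probs, dtype=float)), (d,)
    )
    logmean = np.broadcast_to(np.atleast_1d(np.asarray(config.ads_logmean, dtype=float)), (d,))
    logsd = np.broadcast_to(np.atleast_1d(np.asarray(config.ads_logsd, dtype=float)), (d,))
    exposed = r_expo.random((n, d)) < expo_probs[None, :]
    ads = np.where(
        exposed,
        np.exp(logmean[None, :] + logsd[None, :] * r_expo.standard_normal((n, d))),
        0.0,
    )
    # generative dose codes use the theoretical lognormal median per drug
    gen_median = np.exp(logmean)
    codes = np.zeros((n, d), dtype=np.int64)
    codes[(ads > 0) & (ads <= gen_median[None, :])] = 1
    codes[ads > gen_median[None, :]] = 2

    # --- outcome model ---------------------------------------------------
    nuisance = np.broadcast_to(
        np.atleast_1d(np.asarray(config.nuisance_main_effects, dtype=float)), (d,)
    )
    lp = np.full(n, logit(config.outcome_prevalence))
    lp += codes @ nuisance
    for triplet, beta in config.planted_effects:
        lp += design_matrix(codes[:, list(triplet)]) @ np.asarray(beta, dtype=float)
    if config.stratum_sd > 0:
        birth_date = (birth_year - 1970).astype("datetime64[Y]").astype("datetime64[D]")
        age = (
            (index_date - birth_date).astype("timedelta64[D]").astype(np.int64) / 365.25
        ).astype(np.int64)
        month_idx = index_date.astype("datetime64[M]").astype(np.int64)
        cell = pd.MultiIndex.from_arrays(
            [gender, race, *(rf[:, j] for j in range(n_rf)), age // 3, month_idx // 3]
        )
        cell_codes, uniques = pd.factorize(cell)
        intercepts = config.stratum_sd * r_outcome.standard_normal(len(uniques))
        lp += intercepts[cell_codes]
    is_case = r_outcome.random(n) < expit(lp)

    # --- diagnoses table -------------------------------------------------
    frames = []
    # index ED visit, position 1
    frames.append(
        pd.DataFrame(
            {
                "person_id": person_id,
                "date": index_date,
                "code": np.where(is_case, "ADE", "OTHER"),
                "position": 1,
                "ed_flag": 1,
            }
        )
    )
    # a secondary diagnosis at the same visit, position 2
    frames.append(
        pd.DataFrame(
            {
                "person_id": person_id,
                "date": index_date,
                "code": "OTHER2",
                "position": 2,
                "ed_flag": 1,
            }
        )
    )
    # risk-factor history strictly before index
    for j in range(n_rf):
        has = rf[:, j] == 1
        if has.any():
            back = r_history.integers(200, 1000, size=int(has.sum()))
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": person_id[has],
                        "date": index_date[has] - back.astype("timedelta64[D]"),
                        "code": f"RF{j}",
                        "position": 1,
                        "ed_flag": 0,
                    }
                )
            )
    # recent prior ED visit (violates the 180-day washout)
    recent_ed = r_history.random(n) < config.prior_ed_frac
    if recent_ed.any():
        back = r_history.integers(30, 180, size=int(recent_ed.sum()))
        frames.append(
            pd.DataFrame(
                {
                    "person_id": person_id[recent_ed],
                    "date": index_date[recent_ed] - back.astype("timedelta64[D]"),
                    "code": "OTHER",
                    "position": 1,
                    "ed_flag": 1,
                }
            )
        )
    # prior adverse-event diagnosis (violates the prior-outcome exclusion)
    prior_ade = r_history.random(n) < config.prior_ade_frac
    if prior_ade.any():
        back = r_history.integers(400, 1000, size=int(prior_ade.sum()))
        frames.append(
            pd.DataFrame(
                {
                    "person_id": person_id[prior_ade],
                    "date": index_date[prior_ade] - back.astype("timedelta64[D]"),
                    "code": "ADE",
                    "position": 1,
                    "ed_flag": 0,
                }
            )
        )
    diagnoses = pd.concat(frames, ignore_index=True)
    diagnoses = diagnoses.sort_values(["person_id", "date", "position"]).reset_index(
        drop=True
    )

    # --- pharmacy claims -------------------------------------------------
    units = config.drug_units()
    pi, di = np.nonzero(exposed)
    m = pi.shape[0]
    ads_flat = ads[pi, di]
    two_fills = r_claims.random(m) < 0.3
    rows = {key: [] for key in (
        "person_id", "fill_date", "ingredient", "unit",
        "dose_per_unit", "quantity", "days_supply",
    )}
    day_choices = np.array([7, 14, 30])

    def _append(mask_idx, ads_vals):
        k = mask_idx.shape[0]
        days = day_choices[r_claims.integers(0, 3, size=k)]
        upd = r_claims.integers(1, 3, size=k)  # units per day
        back = r_claims.integers(1, 30, size=k)
        rows["person_id"].append(person_id[pi[mask_idx]])
        rows["fill_date"].append(
            index_date[pi[mask_idx]] - back.astype("timedelta64[D]")
        )
        rows["ingredient"].append(
            np.array([units[j][0] for j in di[mask_idx]])
        )
        rows["unit"].append(np.array([units[j][1] for j in di[mask_idx]]))
        rows["dose_per_unit"].append(ads_vals / upd)
        rows["quantity"].append((upd * days).astype(float))
        rows["days_supply"].append(days)

    idx_all = np.arange(m)
    _append(idx_all, ads_flat)  # first (or only) in-window fill
    idx_two = idx_all[two_fills]
    if idx_two.size:
        _append(idx_two, ads_flat[two_fills])  # second fill, same true ADS
    # out-of-window noise fills: present in the table, ignored by the window
    noise = r_claims.random(m) < 0.2
    idx_noise = idx_all[noise]
    if idx_noise.size:
        k = idx_noise.shape[0]
        days = day_choices[r_claims.integers(0, 3, size=k)]
        back = r_claims.integers(40, 120, size=k)
        rows["person_id"].append(person_id[pi[idx_noise]])
        rows["fill_date"].append(
            index_date[pi[idx_noise]] - back.astype("timedelta64[D]")
        )
        rows["ingredient"].append(np.array([units[j][0] for j in di[idx_noise]]))
        rows["unit"].append(np.array([units[j][1] for j in di[idx_noise]]))
        rows["dose_per_unit"].append(
            np.exp(r_claims.standard_normal(k) + 3.0)
        )
        rows["quantity"].append(days.astype(float))
        rows["days_supply"].append(days)

    claims = pd.DataFrame({key: np.concatenate(vals) for key, vals in rows.items()})
    claims = claims.sort_values(["person_id", "fill_date", "ingredient"]).reset_index(
        drop=True
    )
    return persons, diagnoses, claims


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_fixture(tables: dict, directory, config=None) -> dict:
    """Write tables as CSV files plus a manifest recording config and seed.

    ``tables`` maps a base name (e.g. ``"persons"``) to a DataFrame; dates
    are written in ISO-8601.  Returns a dict of written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in tables.items():
        path = directory / f"{name}.csv"
        out = frame.copy()
        for col in out.columns:
            if np.issubdtype(out[col].dtype, np.datetime64):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        paths[name] = path
    manifest = {"config": _jsonable(config) if config is not None else None}
    if config is not None and hasattr(config, "seed"):
        manifest["seed"] = int(config.seed)
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = mpath
    return paths
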