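"""End-to-end pipeline: simulate/ingest -> cohort -> exposure -> screen
-> profile -> report.

Each stage reads only the previous stage's files inside a run directory
and writes CSV/JSON artifacts plus counters into ``manifest.json``, so
stages are independently runnable and a completed run is reproducible
from its manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, exposure, profiling, screening, simulate
from .errors import ConfigurationError, ReportError

FAILED_MARKER = "FAILED"


@dataclass
class PipelineConfig:
    """One run's inputs, outcome definition, policy and seed.

    Exactly one of ``input_tables`` (paths to persons/diagnoses/claims
    CSVs) or ``simulation`` (a :class:`~trioscreen.simulate.SimConfig`)
    must be supplied.
    """

    outcome: cohort.OutcomeDefinition
    simulation: simulate.SimConfig | None = None
    input_tables: dict | None = None
    policy: screening.ScreeningPolicy = field(
        default_factory=screening.ScreeningPolicy
    )
    window_days: int = exposure.DEFAULT_WINDOW_DAYS
    seed: int = 0
    subgroup_min_age: int | None = None

    def __post_init__(self):
        if (self.simulation is None) == (self.input_tables is None):
            raise ConfigurationError(
                "exactly one of input_tables or simulation must be supplied"
            )

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "PipelineConfig":
        outcome_raw = raw["outcome"]
        outcome = cohort.OutcomeDefinition(
            ade_name=outcome_raw["ade_name"],
            ade_codes=outcome_raw["ade_codes"],
            risk_factor_map=outcome_raw.get("risk_factor_map", {}),
            risk_factor_labels=outcome_raw.get("risk_factor_labels"),
        )
        sim = None
        if "simulation" in raw:
            sim_raw = dict(raw["simulation"])
            planted = [
                (tuple(e["triplet"]), tuple(e["beta"]))
                for e in sim_raw.pop("planted_effects", [])
            ]
            sim = simulate.SimConfig(planted_effects=planted, **sim_raw)
        pol_raw = dict(raw.get("policy", {}))
        if "required_drug_set" in pol_raw:
            pol_raw["required_drug_set"] = frozenset(pol_raw["required_drug_set"])
        policy = screening.ScreeningPolicy(**pol_raw)
        cfg = cls(
            outcome=outcome,
            simulation=sim,
            input_tables=raw.get("input_tables"),
            policy=policy,
            window_days=raw.get("window_days", exposure.DEFAULT_WINDOW_DAYS),
            seed=raw.get("seed", 0),
            subgroup_min_age=raw.get("subgroup_min_age"),
        )
        if seed is not None:
            cfg.seed = seed
            if cfg.simulation is not None:
                cfg.simulation.seed = seed
        return cfg

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, seed=seed)


def demo_config_dict() -> dict:
    """The bundled demonstration configuration as a plain dict."""
    text = resources.files("trioscreen").joinpath("data/demo_config.yaml").read_text()
    return yaml.safe_load(text)


def demo_config(seed: int | None = None) -> PipelineConfig:
    return PipelineConfig.from_dict(demo_config_dict(), seed=seed)


def _update_manifest(outdir: Path, **entries) -> dict:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    for key, value in entries.items():
        if key == "counts" and "counts" in manifest:
            manifest["counts"].update(value)
        else:
            manifest[key] = value
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def stage_input(config: PipelineConfig, outdir: Path) -> tuple:
    """Simulate tables or load them from the configured CSV paths."""
    if config.simulation is not None:
        persons, diagnoses, claims = simulate.generate_population(config.simulation)
        simulate.write_fixture(
            {"persons": persons, "diagnoses": diagnoses, "claims": claims},
            outdir,
            config=config.simulation,
        )
    else:
        persons = pd.read_csv(config.input_tables["persons"])
        diagnoses = pd.read_csv(config.input_tables["diagnoses"])
        claims = pd.read_csv(config.input_tables["claims"])
    diagnoses["date"] = pd.to_datetime(diagnoses["date"])
    claims["fill_date"] = pd.to_datetime(claims["fill_date"])
    persons["enroll_start"] = pd.to_datetime(persons["enroll_start"])
    persons["enroll_end"] = pd.to_datetime(persons["enroll_end"])
    _update_manifest(
        outdir,
        seed=config.seed,
        counts={"persons": int(len(persons)), "diagnosis_rows": int(len(diagnoses)),
                "claim_rows": int(len(claims))},
    )
    return persons, diagnoses, claims


def stage_cohort(config: PipelineConfig, outdir: Path, persons, diagnoses):
    cases = cohort.identify_cases(persons, diagnoses, config.outcome)
    pool = cohort.eligible_controls(persons, diagnoses, config.outcome)
    pairs, unmatched = cohort.match_controls(cases, pool)
    frame = cohort.pairs_frame(pairs)
    if config.subgroup_min_age is not None:
        frame = screening.subgroup_filter(frame, config.subgroup_min_age)
    frame.to_csv(outdir / "pairs.csv", index=False)
    pd.DataFrame(
        [{"person_id": c.person_id, "index_date": c.index_date} for c in unmatched]
    ).to_csv(outdir / "unmatched_cases.csv", index=False)
    _update_manifest(
        outdir,
        counts={
            "cases_identified": len(cases),
            "control_pool": len(pool),
            "pairs_matched": len(pairs),
            "cases_unmatched": len(unmatched),
            "pairs_after_subgroup": int(frame["pair_id"].nunique()) if len(frame) else 0,
        },
    )
    return frame


def stage_exposure(config: PipelineConfig, outdir: Path, claims, pairs_frame):
    lookup = pairs_frame[["pair_id", "role", "person_id", "index_date"]]
    ads_long = exposure.ads_table(claims, lookup, config.window_days)
    case_ads = ads_long[ads_long["role"] == "case"]
    drug_units = exposure.select_top_drug_units(case_ads, k=config.policy.top_k)
    thresholds = exposure.compute_thresholds(case_ads, drug_units)
    pd.DataFrame(
        [
            {
                "ingredient": t.ingredient,
                "unit": t.unit,
                "median_ads": t.median_ads,
                "n_exposed_cases": t.n_exposed_cases,
            }
            for t in thresholds
        ]
    ).to_csv(outdir / "thresholds.csv", index=False)
    matrix = exposure.build_dose_matrix(ads_long, thresholds, pairs_frame)
    matrix.to_csv(outdir / "dose_matrix.csv", index=False)
    _update_manifest(
        outdir,
        counts={"drug_units_retained": len(thresholds)},
    )
    return matrix


def stage_screen(config: PipelineConfig, outdir: Path, dose_matrix):
    outcome = screening.screen(dose_matrix, config.policy)
    screening.results_frame(outcome).to_csv(outdir / "screening_results.csv", index=False)
    signals = [
        {
            "triplet": list(res.triplet),
            "or_222": res.or_222,
            "q_composite": res.q_values["composite_222"],
        }
        for res in outcome.signals
    ]
    (outdir / "signals.json").write_text(json.dumps(signals, indent=2))
    (outdir / "fits.json").write_text(
        json.dumps([res.fit.to_record() for res in outcome.results], indent=2)
    )
    _update_manifest(
        outdir,
        counts={
            "triplets_tested": len(outcome.results),
            "triplets_quarantined": len(outcome.quarantined),
            "signals": len(outcome.signals),
        },
    )
    return outcome


def stage_profile(config: PipelineConfig, outdir: Path, outcome):
    profiles = [profiling.build_profile(res.fit) for res in outcome.signals]
    profiling.profiles_frame(profiles).to_csv(outdir / "profiles.csv", index=False)
    medians = profiling.summarize_medians(profiles)
    profiling.medians_frame(medians).to_csv(outdir / "medians.csv", index=False)
    return profiles


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every stage; on failure, leave a FAILED marker naming it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / FAILED_MARKER
    if marker.exists():
        marker.unlink()
    stage = "input"
    try:
        persons, diagnoses, claims = stage_input(config, outdir)
        stage = "cohort"
        pairs = stage_cohort(config, outdir, persons, diagnoses)
        stage = "exposure"
        matrix = stage_exposure(config, outdir, claims, pairs)
        stage = "screen"
        outcome = stage_screen(config, outdir, matrix)
        stage = "profile"
        stage_profile(config, outdir, outcome)
        stage = "report"
        render_report(outdir)
    except Exception as err:
        marker.write_text(f"stage: {stage}\nerror: {err}\n")
        raise
    return outdir


def render_report(run_dir) -> str:
    """Human-readable markdown report summarising a completed run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists() or (run_dir / FAILED_MARKER).exists():
        raise ReportError("run directory is incomplete or failed")
    for required in ("pairs.csv", "screening_results.csv", "medians.csv"):
        if not (run_dir / required).exists():
            raise ReportError(f"missing stage output: {required}")
    manifest = json.loads(manifest_path.read_text())
    counts = manifest.get("counts", {})
    pairs = pd.read_csv(run_dir / "pairs.csv")
    signals = json.loads((run_dir / "signals.json").read_text())

    lines = ["# Screening run report", ""]
    lines.append("## Cohort")
    n_pairs = int(pairs["pair_id"].nunique()) if len(pairs) else 0
    lines.append(f"- matched pairs: {n_pairs}")
    if len(pairs):
        cases = pairs[pairs["role"] == "case"]
        pct_f = 100.0 * (cases["gender"] == "F").mean()
        lines.append(f"- case median age: {cases['age_at_index'].median():.0f} years")
        lines.append(f"- female cases: {pct_f:.1f}%")
    for key in ("cases_identified", "cases_unmatched", "triplets_tested",
                "triplets_quarantined", "signals"):
        if key in counts:
            lines.append(f"- {key.replace('_', ' ')}: {counts[key]}")
    lines.append("")
    lines.append("## Signals")
    if not signals:
        lines.append("No adverse three-drug-combination signals were selected.")
    else:
        lines.append("| triplet | OR(2,2,2) | composite q |")
        lines.append("|---|---|---|")
        for sig in signals:
            lines.append(
                f"| {' + '.join(sig['triplet'])} | {sig['or_222']:.2f} "
                f"| {sig['q_composite']:.3g} |"
            )
        profiles = pd.read_csv(run_dir / "profiles.csv", dtype={"config": str})
        medians = pd.read_csv(run_dir / "medians.csv")
        if len(medians):
            lines.append("")
            lines.append("## Median odds ratios by dose stratum")
            lines.append("| stratum | median OR | n |")
            lines.append("|---|---|---|")
            for row in medians.itertuples():
                lines.append(f"| {row.stratum} | {row.median_or:.2f} | {row.n} |")
        if len(profiles):
            lines.append("")
            lines.append("## Dose profiles")
            for (d1, d2, d3), block in profiles.groupby(["drug1", "drug2", "drug3"]):
                lines.append(f"### {d1} + {d2} + {d3}")
                lines.append("| config | OR | 95% CI |")
                lines.append("|---|---|---|")
                for row in block.sort_values("config").itertuples():
                    lines.append(
                        f"| {row.config} | {row.odds_ratio:.2f} "
                        f"| ({row.ci_low:.2f}, {row.ci_high:.2f}) |"
                    )
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
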