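"""End-to-end pipeline: generate → derive → fit → calibrate → simulate → cea.

Each stage reads its inputs from the output directory and writes plain CSV
or JSON artifacts, so stages can be toggled and rerun independently.  A
manifest records the configuration hash, master seed, package version, and
per-stage row counts; reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from scdsim import __version__
from scdsim.calibration import (
    CalibrationTarget,
    calibrate_to_prevalence,
    targets_from_table,
)
from scdsim.cohort import CohortDefinition, build_panel, lifetime_prevalence
from scdsim.config import RunConfig
from scdsim.economics import (
    PSASpec,
    compare_strategies,
    evaluate_trajectory,
    run_psa,
)
from scdsim.engine import (
    SimulationModels,
    Trajectory,
    YearRecord,
    run_cohort,
)
from scdsim.indices import (
    PenaltySpec,
    PredictionIndex,
    SplitSpec,
    bootstrap_uncertainty,
    build_design,
    fit_index,
    load_indices,
    save_bootstrap,
    save_indices,
    split_sample,
)
from scdsim.features import TREATMENT_FLAGS, UTILIZATION_CATEGORIES, panel_blocks
from scdsim.registry import AttributeRegistry
from scdsim.rng import substream
from scdsim.synthetic import (
    combined_scenario_configs,
    concat_tables,
    generate_population,
    read_claims,
    scenario_config,
    write_claims,
)

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("scdsim")

STAGE_ORDER = ("generate", "derive", "fit", "calibrate", "simulate", "cea")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(stage, f"missing prerequisite {path.name}")
    return path


# ---------------------------------------------------------------------------
# trajectory (de)serialization


def trajectories_to_frame(trajs: list[Trajectory], models: SimulationModels) -> pd.DataFrame:
    rows = []
    for pid, t in enumerate(trajs):
        for rec in t.records:
            row = {
                "person": pid,
                "strategy": t.strategy,
                "sex_female": int(t.sex_female),
                "birth_year": t.birth_year,
                "entry_age": round(t.entry_age, 4),
                "payer": t.payer,
                "strategy_received": t.strategy_received or "",
                "cured": int(t.cured),
                "one_time_cost": t.one_time_cost,
                "year_index": rec.year_index,
                "age": rec.age,
                "died": int(rec.died),
            }
            for i, name in enumerate(models.dis_names):
                row[f"attr_{name}"] = int(rec.dis_flags[i])
            for j, name in enumerate(models.comp_names):
                row[f"comp_{name}"] = int(rec.comp_flags[j])
            for k, name in enumerate(TREATMENT_FLAGS):
                row[f"tx_{name}"] = int(rec.tx_flags[k])
            for k, name in enumerate(UTILIZATION_CATEGORIES):
                row[f"util_{name}"] = int(rec.util[k])
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_trajectories(df: pd.DataFrame, models: SimulationModels) -> list[Trajectory]:
    trajs = []
    for _, g in df.groupby("person", sort=True):
        g = g.sort_values("year_index")
        first = g.iloc[0]
        records = []
        for _, r in g.iterrows():
            records.append(YearRecord(
                year_index=int(r["year_index"]), age=float(r["age"]),
                dis_flags=np.array([r[f"attr_{n}"] for n in models.dis_names], dtype=float),
                comp_flags=np.array([r[f"comp_{n}"] for n in models.comp_names], dtype=float),
                tx_flags=np.array([r[f"tx_{n}"] for n in TREATMENT_FLAGS], dtype=float),
                util=np.array([r[f"util_{n}"] for n in UTILIZATION_CATEGORIES], dtype=float),
                acute_events=(), died=bool(r["died"]),
            ))
        trajs.append(Trajectory(
            sex_female=bool(first["sex_female"]), birth_year=int(first["birth_year"]),
            entry_age=float(first["entry_age"]), payer=str(first["payer"]),
            strategy=str(first["strategy"]),
            strategy_received=str(first["strategy_received"]) or None,
            cured=bool(first["cured"]), one_time_cost=float(first["one_time_cost"]),
            records=records,
        ))
    return trajs


# ---------------------------------------------------------------------------
# stages


def stage_generate(cfg: RunConfig, out: Path, registry: AttributeRegistry) -> dict:
    if cfg.scenario == "combined":
        parts = [
            generate_population(
                scenario_config(c.payer, n=c.n_beneficiaries, seed=cfg.seed,
                                **cfg.generator_overrides),
                registry,
            )
            for c in combined_scenario_configs(cfg.n_beneficiaries, seed=cfg.seed)
        ]
        tables = concat_tables(parts)
    else:
        tables = generate_population(
            scenario_config(cfg.scenario, n=cfg.n_beneficiaries, seed=cfg.seed,
                            **cfg.generator_overrides),
            registry,
        )
    write_claims(tables, out / "claims")
    return {
        "beneficiaries": len(tables.beneficiaries),
        "enrollment_spans": len(tables.enrollment),
        "claims": len(tables.claims),
    }


def stage_derive(cfg: RunConfig, out: Path, registry: AttributeRegistry) -> dict:
    tables = read_claims(_require(out / "claims", "derive"))
    panel, attrition = build_panel(tables, registry, CohortDefinition())
    if len(panel) == 0:
        raise PipelineError("derive", "no beneficiaries survived cohort filters")
    panel.to_csv(out / "panel.csv", index=False)
    prev = lifetime_prevalence(panel, registry)
    prev.to_csv(out / "prevalence.csv")
    (out / "attrition.json").write_text(json.dumps(attrition, indent=1))
    for name, count in attrition.items():
        log.info("derive attrition: %s = %d", name, count)
    return {"panel_rows": len(panel), **attrition}


def fit_index_with_fallback(design, spec, panel_rate: float | None = None):
    """Penalized fit; degenerate outcomes fall back to an intercept-only
    index at a Laplace-smoothed event rate so every outcome stays drawable
    (calibration adjusts levels afterwards)."""
    try:
        return fit_index(design, spec), False
    except ValueError:
        n = max(len(design), 1)
        events = float(design.y.sum()) if len(design) else 0.0
        rate = (events + 0.5) / (n + 1.0)
        intercept = float(np.log(rate / (1.0 - rate)))
        return PredictionIndex(
            design.outcome_name, design.family, "logit", intercept,
            {name: 0.0 for name in design.X.columns},
            {"kind": "intercept_only", "strength": None},
        ), True


def stage_fit(cfg: RunConfig, out: Path, registry: AttributeRegistry) -> dict:
    panel = pd.read_csv(_require(out / "panel.csv", "fit"))
    train, test1, _test2 = split_sample(panel, SplitSpec(seed=cfg.seed))
    spec = PenaltySpec(
        kind=cfg.penalty_kind, l1_ratio=cfg.l1_ratio,
        strength=cfg.penalty_strength, strength_grid=cfg.cv_grid,
        cv_folds=cfg.cv_folds, seed=cfg.seed,
    )
    blocks = panel_blocks(train, registry)
    indices: dict[str, PredictionIndex] = {}
    n_fallback = 0
    outcomes = (
        [(a.name, "incidence") for a in registry.disease_attributes]
        + [(t, "treatment_use") for t in TREATMENT_FLAGS]
        + [(a.name, "complication") for a in registry.complication_attributes]
        + [(u, "utilization") for u in UTILIZATION_CATEGORIES]
    )
    outcomes = [(o, f) for o, f in outcomes if f in cfg.fit_families]
    for outcome, family in outcomes:
        design = build_design(train, outcome, family, registry, blocks=blocks)
        if family == "utilization":
            ix = fit_index(design, spec)
            fell_back = False
        else:
            ix, fell_back = fit_index_with_fallback(design, spec)
        n_fallback += fell_back
        indices[outcome] = ix
    save_indices(indices, out / "indices.json")

    bsets = {}
    if cfg.bootstrap_replicates > 0 and cfg.bootstrap_outcomes:
        blocks1 = panel_blocks(test1, registry)
        for outcome in cfg.bootstrap_outcomes:
            family = indices[outcome].family
            design = build_design(test1, outcome, family, registry, blocks=blocks1)
            bsets[outcome] = bootstrap_uncertainty(
                design, PenaltySpec(kind=cfg.penalty_kind, l1_ratio=cfg.l1_ratio,
                                    strength=indices[outcome].penalty.get("strength") or cfg.penalty_strength),
                cfg.bootstrap_replicates, seed=cfg.seed,
            )
    save_bootstrap(bsets, out / "bootstrap.json")
    return {
        "indices_fit": len(indices),
        "intercept_only_fallbacks": n_fallback,
        "bootstrap_outcomes": len(bsets),
    }


def _models(cfg: RunConfig, out: Path, registry: AttributeRegistry, calibrated: bool) -> SimulationModels:
    name = "calibrated_indices.json" if calibrated else "indices.json"
    path = out / name
    if calibrated and not path.exists():
        path = out / "indices.json"
    indices = load_indices(_require(path, "simulate"))
    return SimulationModels(registry, indices, cfg.mortality())


def stage_calibrate(cfg: RunConfig, out: Path, registry: AttributeRegistry) -> dict:
    models = _models(cfg, out, registry, calibrated=False)
    column = cfg.calibration_column or (
        cfg.scenario if cfg.scenario in ("medicaid", "medicare", "dual") else "combined"
    )
    if cfg.calibration_targets_path:
        # user-supplied CSV: attribute,payer,target[,tolerance]
        table = pd.read_csv(
            _require(Path(cfg.calibration_targets_path), "calibrate")
        )
        targets = [
            CalibrationTarget(
                attribute=row["attribute"],
                payer=row.get("payer", column),
                target=float(row["target"]),
                tolerance=float(row.get("tolerance", cfg.calibration_tolerance)),
            )
            for _, row in table.iterrows()
        ]
    else:
        targets = targets_from_table(column, tolerance=cfg.calibration_tolerance)
    result = calibrate_to_prevalence(
        models, targets, cfg.population(),
        n_sim=cfg.calibration_n_sim, max_iter=cfg.calibration_max_iter,
        seed=cfg.seed,
    )
    calibrated = models.with_shifts(result.shifts)
    save_indices(calibrated.indices, out / "calibrated_indices.json")
    result.report().to_csv(out / "calibration_report.csv", index=False)
    for flag in result.flags:
        log.warning("calibration: %s", flag)
    return {
        "targets": len(targets),
        "converged": int(sum(result.converged.values())),
        "iterations": result.iterations,
    }


def stage_simulate(cfg: RunConfig, out: Path, registry: AttributeRegistry) -> dict:
    models = _models(cfg, out, registry, calibrated=True)
    strategies = cfg.strategy_objects(registry)
    pop = cfg.population()
    counts = {}
    summaries = []
    for name, strategy in strategies.items():
        seed = int(substream(cfg.seed, "simulate", name).integers(2**31 - 1))
        trajs, summary = run_cohort(
            cfg.n_simulate, pop, strategy, models, seed=seed, collect=True
        )
        frame = trajectories_to_frame(trajs, models)
        frame.to_csv(out / f"trajectories_{name}.csv", index=False)
        counts[name] = len(frame)
        row = {
            "strategy": name, "n": summary.n,
            "mean_survival": summary.mean_survival,
            "events_per_person_year": summary.events_per_person_year,
        }
        row.update({f"prev_{k}": v for k, v in summary.lifetime_prevalence.items()})
        summaries.append(row)
    pd.DataFrame(summaries).to_csv(out / "summary_simulation.csv", index=False)
    return {f"person_years_{k}": v for k, v in counts.items()}


def stage_cea(cfg: RunConfig, out: Path, registry: AttributeRegistry) -> dict:
    models = _models(cfg, out, registry, calibrated=True)
    utility = cfg.utility_index(registry)
    costs = cfg.cost_model()
    discount = cfg.discount()
    evaluations = {}
    for name in cfg.strategies:
        path = _require(out / f"trajectories_{name}.csv", "cea")
        trajs = frame_to_trajectories(pd.read_csv(path), models)
        evaluations[name] = [
            evaluate_trajectory(t, models, utility, costs, discount) for t in trajs
        ]
    result = compare_strategies(evaluations, perspective="societal")
    per = pd.DataFrame(result.per_strategy).T
    per.index.name = "strategy"
    per.to_csv(out / "cea_summary.csv")
    pd.DataFrame(result.icers).to_csv(out / "icers.csv", index=False)

    info = {"strategies": len(evaluations)}
    if cfg.psa_draws > 0:
        strategies = cfg.strategy_objects(registry)
        names = list(cfg.strategies)
        psa = run_psa(
            models,
            (strategies[names[0]], strategies[names[1]]),
            cfg.population(), utility, costs,
            PSASpec(n_draws=cfg.psa_draws, cohort_n=cfg.psa_cohort_n),
            discount=discount,
            seed=cfg.seed,
        )
        pd.DataFrame(psa["cloud"], columns=["delta_cost", "delta_qalys"]).to_csv(
            out / "psa_draws.csv", index=False
        )
        pd.DataFrame(psa["ceac"], columns=["wtp", "prob_cost_effective"]).to_csv(
            out / "ceac.csv", index=False
        )
        info["psa_draws"] = cfg.psa_draws
    return info


# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages in order; returns the output directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    registry = cfg.registry()
    stage_fns = {
        "generate": stage_generate,
        "derive": stage_derive,
        "fit": stage_fit,
        "calibrate": stage_calibrate,
        "simulate": stage_simulate,
        "cea": stage_cea,
    }
    unknown = set(cfg.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        log.info("running stage %s", stage)
        try:
            info = stage_fns[stage](cfg, out, registry)
        except PipelineError:
            raise
        except Exception as exc:  # halt with stage name and cause
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = info
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
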