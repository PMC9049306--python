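"""Costs, QALYs, ICERs, and probabilistic sensitivity analysis.

Trajectories from the simulation engine are valued under two perspectives:

* healthcare sector — utilization priced at unit costs, annual treatment
  costs, one-time curative-therapy prices, future unrelated medical costs,
  and end-of-life costs;
* societal — the above plus time-use costs (lost market and non-market
  productive time, valued linearly in the utility shortfall at a wage-plus-
  fringe rate) and unpaid caregiver time.

Annual health-state utility is a base value (declining gently with adult
age) minus additive decrements for each active condition, chronic pain
applied in parallel with everything else, clamped to [0, 1].  Optional
pairwise interaction terms can offset double counting.  Both costs and
QALYs are discounted at a configurable annual rate (default 3%/year, the
U.S. reference-case convention).  The death year is valued as a full lived
year, matching the engine's annual-cycle convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from scdsim.engine import (
    PopulationSpec,
    SimulationModels,
    Strategy,
    Trajectory,
    YearRecord,
    run_cohort,
)
from scdsim.indices import BootstrapSet, PredictionIndex
from scdsim.registry import AttributeRegistry
from scdsim.rng import substream

__all__ = [
    "UtilityIndex",
    "CostModel",
    "DiscountSpec",
    "CEAResult",
    "annual_utility",
    "annual_cost",
    "discount_stream",
    "evaluate_trajectory",
    "compare_strategies",
    "run_psa",
    "default_utility_index",
    "default_cost_model",
]

MEDICAL_COMPONENTS = ("medical", "treatment", "therapy_price", "future_unrelated", "end_of_life")
SOCIETAL_EXTRA = ("time_use", "caregiver")
UTILIZATION_ORDER = ("inpatient", "ed", "outpatient")


@dataclass
class UtilityIndex:
    """Additive health-state-utility model with clamping."""

    base_by_age: tuple[float, float, float] = (0.92, 18.0, 0.001)
    # (base, pivot age, per-year decline past the pivot)
    sex_female_offset: float = 0.0
    decrements: dict[str, float] = field(default_factory=dict)
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    known_attributes: frozenset[str] = frozenset()
    floor: float = 0.0
    cap: float = 1.0

    def base(self, age: float, sex_female: bool = False) -> float:
        b0, pivot, slope = self.base_by_age
        base = b0 - slope * max(0.0, age - pivot)
        return base + (self.sex_female_offset if sex_female else 0.0)


def default_utility_index(registry: AttributeRegistry) -> UtilityIndex:
    decrements = {
        "chronic_pain": 0.10,
        "vaso_occlusive_pain_episodes": 0.06,
        "stroke": 0.12,
        "acute_chest_syndrome": 0.05,
        "infections": 0.02,
        "fever": 0.01,
        "acute_renal_failure": 0.04,
        "multi_organ_failure": 0.15,
        "bacteremia_and_sepsis": 0.05,
        "acute_anemia": 0.02,
        "splenic_disease": 0.02,
        "priapism": 0.02,
        "dactylitis": 0.02,
        "myocardial_infarction": 0.08,
        "fatigue": 0.04,
        "asthma": 0.03,
        "leg_ulcers": 0.05,
        "hepatobiliary_complications_and_liver_disease": 0.04,
        "sleep_disordered_breathing": 0.04,
        "depression_and_unspecified_psychosis": 0.07,
        "chronic_renal_disease": 0.08,
        "pulmonary_hypertension_and_cardiovascular_diseases": 0.08,
        "chronic_lung_diseases": 0.06,
        "ocular_complications": 0.03,
        "cognitive_impairment": 0.07,
        "avascular_necrosis_and_bone_damage": 0.06,
        # complications
        "graft_versus_host_disease": 0.10,
        "graft_failure": 0.08,
        "iron_overload": 0.03,
        "bronchiolitis_obliterans": 0.06,
        "secondary_malignancy": 0.12,
        "post_treatment_depression": 0.06,
        "posterior_reversible_encephalopathy_syndrome": 0.05,
        "post_transplant_lymphoproliferative_disorder": 0.08,
        "osteoporosis": 0.03,
        "leukopenia": 0.01,
        "thrombocytopenia": 0.02,
        "oligospermia_azospermia": 0.02,
        "transfusion_reaction": 0.02,
        "transfusion_infection": 0.03,
    }
    return UtilityIndex(
        decrements=decrements,
        known_attributes=frozenset(registry.attributes),
    )


@dataclass
class CostModel:
    """Unit costs and non-medical cost coefficients (2019 US dollars)."""

    unit_costs: dict[str, float] = field(
        default_factory=lambda: {"inpatient": 15000.0, "ed": 1500.0, "outpatient": 300.0}
    )
    treatment_annual_costs: dict[str, float] = field(
        default_factory=lambda: {
            "hydroxyurea": 1200.0,
            "acute_transfusion": 3000.0,
            "chronic_transfusion": 40000.0,
        }
    )
    # annual productive hours lost per unit utility shortfall, valued at wage
    time_use_hours: float = 1000.0
    wage_rate: float = 40.0  # mean wage plus fringe benefits, $/hour
    caregiver_cost_child: float = 12000.0  # unpaid caregiver time, age < 18
    caregiver_cost_dependent: float = 8000.0  # adults with utility < threshold
    dependency_threshold: float = 0.5
    future_unrelated_base: float = 3000.0
    future_unrelated_age_coef: float = 80.0  # $/year of age
    end_of_life_cost: float = 30000.0

    def validate(self) -> None:
        values = list(self.unit_costs.values()) + list(self.treatment_annual_costs.values())
        if any(v < 0 for v in values):
            raise ValueError("unit costs must be non-negative")


def default_cost_model() -> CostModel:
    return CostModel()


@dataclass
class DiscountSpec:
    rate: float = 0.03

    def __post_init__(self) -> None:
        if self.rate <= -1:
            raise ValueError("discount rate must exceed -1")


# ---------------------------------------------------------------------------
# per-year valuation


def annual_utility(snapshot, index: UtilityIndex, age: float = 0.0,
                   sex_female: bool = False) -> float:
    """Base utility minus decrements of active conditions, clamped.

    ``snapshot`` is an iterable of active attribute names (or a mapping
    name -> active flag).  Unknown attribute names raise ``KeyError``.
    """
    if isinstance(snapshot, Mapping):
        active = [name for name, flag in snapshot.items() if flag]
    else:
        active = list(snapshot)
    if index.known_attributes:
        for name in active:
            if name not in index.known_attributes:
                raise KeyError(f"unknown attribute {name!r} in snapshot")
    u = index.base(age, sex_female)
    for name in active:
        u -= index.decrements.get(name, 0.0)
    active_set = set(active)
    for (a, b), term in index.interactions.items():
        if a in active_set and b in active_set:
            u += term
    return float(min(index.cap, max(index.floor, u)))


def record_active_names(record: YearRecord, models: SimulationModels) -> list[str]:
    names = [models.dis_names[i] for i in np.nonzero(record.dis_flags)[0]]
    names += [models.comp_names[j] for j in np.nonzero(record.comp_flags)[0]]
    return names


def annual_cost(
    record: YearRecord,
    cost_model: CostModel,
    perspective: str = "societal",
    utility: float | None = None,
    age: float | None = None,
) -> dict[str, float]:
    """Cost breakdown for one person-year under the given perspective.

    The societal perspective includes the healthcare-sector components plus
    time-use and caregiver costs; the difference between perspectives is
    exactly the sum of the non-medical components.
    """
    if perspective not in ("societal", "healthcare"):
        raise ValueError(f"unknown perspective {perspective!r}")
    util = record.util
    if (util < 0).any():
        raise ValueError("negative utilization count")
    age = record.age if age is None else age
    medical = float(sum(
        cost_model.unit_costs[cat] * util[k]
        for k, cat in enumerate(UTILIZATION_ORDER)
    ))
    treatment = float(sum(
        cost_model.treatment_annual_costs[t] * record.tx_flags[k]
        for k, t in enumerate(("hydroxyurea", "acute_transfusion", "chronic_transfusion"))
    ))
    out = {
        "medical": medical,
        "treatment": treatment,
        "future_unrelated": cost_model.future_unrelated_base
        + cost_model.future_unrelated_age_coef * age,
        "end_of_life": cost_model.end_of_life_cost if record.died else 0.0,
    }
    if perspective == "societal":
        u = 1.0 if utility is None else utility
        out["time_use"] = (1.0 - u) * cost_model.time_use_hours * cost_model.wage_rate
        if age < 18:
            out["caregiver"] = cost_model.caregiver_cost_child
        elif utility is not None and utility < cost_model.dependency_threshold:
            out["caregiver"] = cost_model.caregiver_cost_dependent
        else:
            out["caregiver"] = 0.0
    return out


def discount_stream(values: Iterable[float], spec: DiscountSpec | float = 0.03) -> float:
    """Present value of an annual stream indexed from year 0."""
    rate = spec.rate if isinstance(spec, DiscountSpec) else float(spec)
    values = np.asarray(list(values), dtype=float)
    if len(values) == 0:
        return 0.0
    t = np.arange(len(values))
    return float(np.sum(values / (1.0 + rate) ** t))


# ---------------------------------------------------------------------------
# trajectory and strategy valuation


def evaluate_trajectory(
    traj: Trajectory,
    models: SimulationModels,
    utility_index: UtilityIndex,
    cost_model: CostModel,
    spec: DiscountSpec | None = None,
) -> dict[str, float]:
    """Discounted QALYs, life years, and cost components for one person."""
    spec = spec or DiscountSpec()
    utilities, comps = [], []
    for rec in traj.records:
        active = record_active_names(rec, models)
        u = annual_utility(active, utility_index, age=rec.age, sex_female=traj.sex_female)
        utilities.append(u)
        comps.append(annual_cost(rec, cost_model, "societal", utility=u, age=rec.age))
    out = {
        "life_years": float(len(utilities)),
        "qalys": discount_stream(utilities, spec),
        "life_years_discounted": discount_stream([1.0] * len(utilities), spec),
    }
    for key in MEDICAL_COMPONENTS + SOCIETAL_EXTRA:
        if key == "therapy_price":
            out[f"cost_{key}"] = traj.one_time_cost  # paid at entry, year 0
        else:
            out[f"cost_{key}"] = discount_stream(
                [c.get(key, 0.0) for c in comps], spec
            )
    out["cost_healthcare"] = sum(out[f"cost_{k}"] for k in MEDICAL_COMPONENTS)
    out["cost_societal"] = out["cost_healthcare"] + sum(
        out[f"cost_{k}"] for k in SOCIETAL_EXTRA
    )
    return out


@dataclass
class CEAResult:
    per_strategy: dict[str, dict[str, float]]  # strategy -> mean outcomes
    icers: list[dict]  # frontier comparisons with dominance flags
    perspective: str = "societal"


def _mean_outcomes(evals: list[dict[str, float]]) -> dict[str, float]:
    keys = evals[0].keys()
    return {k: float(np.mean([e[k] for e in evals])) for k in keys}


def compare_strategies(
    evaluations: dict[str, list[dict[str, float]]],
    perspective: str = "societal",
) -> CEAResult:
    """ICERs on the non-dominated frontier.

    ``evaluations`` maps strategy name to per-person outcome dicts from
    ``evaluate_trajectory``.  Strategies that are more costly and no more
    effective are flagged ``dominated``; those ruled out by extended
    dominance are flagged ``extended_dominated``; equal-QALY comparisons
    are flagged ``undefined`` with the incremental cost reported.
    """
    if len(evaluations) < 2:
        raise ValueError("need at least two strategies")
    cost_key = f"cost_{perspective}"
    means = {name: _mean_outcomes(evals) for name, evals in evaluations.items()}
    order = sorted(means, key=lambda s: (means[s][cost_key], means[s]["qalys"]))

    icers: list[dict] = []
    # simple dominance
    frontier = []
    for s in order:
        if frontier and means[s]["qalys"] <= means[frontier[-1]]["qalys"]:
            icers.append({
                "strategy": s, "comparator": frontier[-1],
                "delta_cost": means[s][cost_key] - means[frontier[-1]][cost_key],
                "delta_qalys": means[s]["qalys"] - means[frontier[-1]]["qalys"],
                "icer": None, "status": "dominated",
            })
            continue
        frontier.append(s)
    # extended dominance: ICERs along the frontier must increase
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for k in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[k - 1], frontier[k], frontier[k + 1]

            def icer(a, b):
                dq = means[b]["qalys"] - means[a]["qalys"]
                dc = means[b][cost_key] - means[a][cost_key]
                return dc / dq if dq != 0 else np.inf

            if icer(lo, mid) > icer(mid, hi):
                icers.append({
                    "strategy": mid, "comparator": lo,
                    "delta_cost": means[mid][cost_key] - means[lo][cost_key],
                    "delta_qalys": means[mid]["qalys"] - means[lo]["qalys"],
                    "icer": None, "status": "extended_dominated",
                })
                frontier.pop(k)
                changed = True
                break
    for a, b in zip(frontier, frontier[1:]):
        dq = means[b]["qalys"] - means[a]["qalys"]
        dc = means[b][cost_key] - means[a][cost_key]
        if dq == 0:
            icers.append({
                "strategy": b, "comparator": a, "delta_cost": dc,
                "delta_qalys": 0.0, "icer": None, "status": "undefined",
            })
        else:
            icers.append({
                "strategy": b, "comparator": a, "delta_cost": dc,
                "delta_qalys": dq, "icer": dc / dq, "status": "frontier",
            })
    return CEAResult(per_strategy=means, icers=icers, perspective=perspective)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSASpec:
    n_draws: int = 50
    cohort_n: int = 200  # reduced-n rerun per draw
    wtp_grid: tuple[float, ...] = tuple(float(w) for w in range(0, 300001, 25000))
    # relative uncertainty applied as multiplicative lognormal factors
    utility_decrement_sd: float = 0.10
    unit_cost_sd: float = 0.10


def _scaled_utility(index: UtilityIndex, factor: float) -> UtilityIndex:
    return UtilityIndex(
        base_by_age=index.base_by_age,
        sex_female_offset=index.sex_female_offset,
        decrements={k: v * factor for k, v in index.decrements.items()},
        interactions=dict(index.interactions),
        known_attributes=index.known_attributes,
        floor=index.floor, cap=index.cap,
    )


def _scaled_costs(model: CostModel, factor: float) -> CostModel:
    return CostModel(
        unit_costs={k: v * factor for k, v in model.unit_costs.items()},
        treatment_annual_costs={
            k: v * factor for k, v in model.treatment_annual_costs.items()
        },
        time_use_hours=model.time_use_hours,
        wage_rate=model.wage_rate,
        caregiver_cost_child=model.caregiver_cost_child,
        caregiver_cost_dependent=model.caregiver_cost_dependent,
        dependency_threshold=model.dependency_threshold,
        future_unrelated_base=model.future_unrelated_base,
        future_unrelated_age_coef=model.future_unrelated_age_coef,
        end_of_life_cost=model.end_of_life_cost,
    )


def _models_from_replicate(
    models: SimulationModels, bootstrap: dict[str, BootstrapSet], draw_rng
) -> SimulationModels:
    if not bootstrap:
        return models
    new_indices = dict(models.indices)
    for name, bset in bootstrap.items():
        if bset.n_replicates == 0 or name not in new_indices:
            continue
        r = int(draw_rng.integers(bset.n_replicates))
        old = new_indices[name]
        new_indices[name] = PredictionIndex(
            old.outcome_name, old.family, old.link,
            float(bset.intercepts[r]),
            dict(zip(bset.feature_list, bset.coefficients[r].tolist())),
            dict(old.penalty),
        )
    return SimulationModels(models.registry, new_indices, models.mortality)


def run_psa(
    models: SimulationModels,
    strategies: tuple[Strategy, Strategy],
    population: PopulationSpec,
    utility_index: UtilityIndex,
    cost_model: CostModel,
    spec: PSASpec,
    bootstrap: dict[str, BootstrapSet] | None = None,
    discount: DiscountSpec | None = None,
    seed: int = 0,
) -> dict:
    """PSA cloud of (Δcost, ΔQALY) draws plus the acceptability curve.

    Each draw samples one bootstrap coefficient replicate per index (when
    available) and multiplicative lognormal factors on utility decrements
    and unit costs, then reruns a reduced-n cohort per strategy with common
    random numbers.  The CEAC is the fraction of draws with positive net
    benefit across the willingness-to-pay grid.
    """
    if spec.n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    comparator, intervention = strategies
    discount = discount or DiscountSpec()
    rng = substream(seed, "psa")
    deltas = []
    for d in range(spec.n_draws):
        u_factor = (
            float(np.exp(rng.normal(0.0, spec.utility_decrement_sd)))
            if spec.utility_decrement_sd > 0 else 1.0
        )
        c_factor = (
            float(np.exp(rng.normal(0.0, spec.unit_cost_sd)))
            if spec.unit_cost_sd > 0 else 1.0
        )
        draw_models = _models_from_replicate(models, bootstrap or {}, rng)
        u_index = _scaled_utility(utility_index, u_factor)
        c_model = _scaled_costs(cost_model, c_factor)
        cohort_seed = int(rng.integers(2**31 - 1))
        results = {}
        for strat in (comparator, intervention):
            trajs, _ = run_cohort(
                spec.cohort_n, population, strat, draw_models,
                seed=cohort_seed, collect=True,
            )
            evals = [
                evaluate_trajectory(t, draw_models, u_index, c_model, discount)
                for t in trajs
            ]
            results[strat.name] = _mean_outcomes(evals)
        deltas.append((
            results[intervention.name]["cost_societal"]
            - results[comparator.name]["cost_societal"],
            results[intervention.name]["qalys"]
            - results[comparator.name]["qalys"],
        ))
    cloud = np.array(deltas)
    return {"cloud": cloud, "ceac": compute_ceac(cloud, spec.wtp_grid)}


def compute_ceac(cloud: np.ndarray, wtp_grid: Iterable[float]) -> list[tuple[float, float]]:
    """Fraction of (Δcost, ΔQALY) draws with positive net benefit per WTP."""
    cloud = np.asarray(cloud, dtype=float)
    return [
        (float(wtp), float(np.mean(wtp * cloud[:, 1] - cloud[:, 0] > 0)))
        for wtp in wtp_grid
    ]
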