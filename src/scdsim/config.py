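"""Run configuration: scenarios, strategies, and pipeline settings.

One YAML file (or a plain dict) drives the whole pipeline.  Every stage
draws from named substreams of a single master seed, so a rerun with the
same configuration reproduces all stochastic outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from scdsim.economics import CostModel, DiscountSpec, UtilityIndex, default_cost_model, default_utility_index
from scdsim.engine import (
    EligibilityRule,
    MortalityModel,
    PopulationSpec,
    Strategy,
    TreatmentEffect,
    common_care,
)
from scdsim.registry import AttributeRegistry, default_registry, load_registry

__all__ = ["RunConfig", "load_config", "scenario_population", "build_strategies", "build_mortality"]

# pooled public-payer demographics (cohort-size weighted)
_POPULATIONS = {
    "medicaid": dict(age_mean=16.9, age_sd=13.9, prop_female=0.534),
    "medicare": dict(age_mean=62.3, age_sd=16.2, prop_female=0.602),
    "dual": dict(age_mean=33.3, age_sd=19.5, prop_female=0.581),
    "commercial": dict(age_mean=28.0, age_sd=16.0, prop_female=0.55),
    "combined": dict(age_mean=27.8, age_sd=21.1, prop_female=0.560),
}

_DEFAULT_MORTALITY_HR = {
    "stroke": 1.5,
    "multi_organ_failure": 2.5,
    "acute_chest_syndrome": 1.3,
    "bacteremia_and_sepsis": 1.4,
    "acute_renal_failure": 1.3,
    "infections": 1.1,
    "chronic_renal_disease": 1.6,
    "pulmonary_hypertension_and_cardiovascular_diseases": 1.5,
    "chronic_lung_diseases": 1.3,
    "graft_versus_host_disease": 1.5,
    "graft_failure": 1.6,
    "secondary_malignancy": 2.0,
}

# curative-therapy effects: responders suppress acute events and chronic
# pain entirely; chronic organ-damage pathways retain half their hazard
_GENE_THERAPY = {
    "p_symptom_free": 0.85,
    "price": 1_800_000.0,
    "acute_risk_ratio": 0.0,
    "chronic_pain_risk_ratio": 0.0,
    "chronic_risk_ratio": 0.5,
    "complications": {
        "graft_failure": (0.05, 0.005),
        "bronchiolitis_obliterans": (0.02, 0.002),
        "osteoporosis": (0.03, 0.005),
        "iron_overload": (0.05, 0.01),
        "post_treatment_depression": (0.10, 0.02),
        "posterior_reversible_encephalopathy_syndrome": (0.03, 0.002),
        "post_transplant_lymphoproliferative_disorder": (0.01, 0.002),
        "secondary_malignancy": (0.01, 0.005),
    },
}
_HSCT = {
    "p_symptom_free": 0.90,
    "price": 250_000.0,
    "acute_risk_ratio": 0.0,
    "chronic_pain_risk_ratio": 0.0,
    "chronic_risk_ratio": 0.5,
    "complications": {
        **_GENE_THERAPY["complications"],
        "graft_versus_host_disease": (0.15, 0.02),
    },
}


def scenario_population(scenario: str, entry_year: int = 2016) -> PopulationSpec:
    if scenario not in _POPULATIONS:
        raise ValueError(f"unknown scenario {scenario!r}")
    d = _POPULATIONS[scenario]
    return PopulationSpec(payer=scenario, entry_year=entry_year, **d)


def build_mortality(overrides: dict | None = None) -> MortalityModel:
    overrides = overrides or {}
    hr = dict(_DEFAULT_MORTALITY_HR)
    hr.update(overrides.get("hazard_ratios", {}))
    return MortalityModel(
        a_female=overrides.get("a_female", 2.4e-4),
        a_male=overrides.get("a_male", 3.0e-4),
        b=overrides.get("b", 0.08),
        hazard_ratios=hr,
    )


def _effect_from_spec(registry: AttributeRegistry, spec: dict) -> TreatmentEffect:
    risk_ratios = {}
    for a in registry.disease_attributes:
        if a.persistence.value == "instantaneous":
            risk_ratios[a.name] = spec["acute_risk_ratio"]
        elif a.name == "chronic_pain":
            risk_ratios[a.name] = spec["chronic_pain_risk_ratio"]
        else:
            risk_ratios[a.name] = spec["chronic_risk_ratio"]
    return TreatmentEffect(
        p_symptom_free=spec["p_symptom_free"],
        risk_ratios=risk_ratios,
        complication_probabilities={
            k: tuple(v) for k, v in spec["complications"].items()
        },
        durability_half_life=spec.get("durability_half_life"),
    )


def build_strategies(
    registry: AttributeRegistry,
    names: list[str] | None = None,
    overrides: dict | None = None,
    eligibility: EligibilityRule | None = None,
) -> dict[str, Strategy]:
    """Strategy objects for the requested names, defaults + YAML overrides."""
    names = names or ["common_care", "gene_therapy"]
    overrides = overrides or {}
    eligibility = eligibility or EligibilityRule()
    base = {"gene_therapy": _GENE_THERAPY, "hsct": _HSCT}
    out: dict[str, Strategy] = {}
    for name in names:
        if name == "common_care":
            out[name] = common_care()
            continue
        if name not in base:
            raise ValueError(f"unknown strategy {name!r}")
        spec = {**base[name], **overrides.get(name, {})}
        out[name] = Strategy(
            name=name,
            effect=_effect_from_spec(registry, spec),
            eligibility=eligibility,
            one_time_cost=float(spec["price"]),
            therapy=name,
        )
    return out


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see ``load_config`` for YAML."""

    seed: int = 0
    outdir: str = "pipeline_out"
    scenario: str = "combined"  # medicaid | medicare | dual | commercial | combined
    registry_path: str | None = None
    stages: tuple[str, ...] = ("generate", "derive", "fit", "calibrate", "simulate", "cea")
    # generate
    n_beneficiaries: int = 2000
    generator_overrides: dict = field(default_factory=dict)
    # fit
    penalty_strength: float = 1.0
    penalty_kind: str = "elastic_net"
    l1_ratio: float = 0.5
    cv_grid: tuple[float, ...] | None = None
    cv_folds: int = 5
    fit_families: tuple[str, ...] = (
        "incidence", "treatment_use", "complication", "utilization"
    )
    bootstrap_outcomes: tuple[str, ...] = ()
    bootstrap_replicates: int = 0
    # calibrate
    calibration_targets_path: str | None = None  # CSV overriding the packaged table
    calibration_column: str | None = None  # defaults to scenario
    calibration_n_sim: int = 3000
    calibration_max_iter: int = 12
    calibration_tolerance: float = 2.0
    # simulate
    n_simulate: int = 2000
    strategies: tuple[str, ...] = ("common_care", "gene_therapy")
    strategy_overrides: dict = field(default_factory=dict)
    mortality_overrides: dict = field(default_factory=dict)
    eligibility_min_events: int = 3
    # cea / psa
    discount_rate: float = 0.03
    psa_draws: int = 0
    psa_cohort_n: int = 200

    def registry(self) -> AttributeRegistry:
        return load_registry(self.registry_path) if self.registry_path else default_registry()

    def population(self) -> PopulationSpec:
        return scenario_population(self.scenario)

    def mortality(self) -> MortalityModel:
        return build_mortality(self.mortality_overrides)

    def strategy_objects(self, registry: AttributeRegistry) -> dict[str, Strategy]:
        return build_strategies(
            registry, list(self.strategies), self.strategy_overrides,
            EligibilityRule(min_severe_events=self.eligibility_min_events),
        )

    def utility_index(self, registry: AttributeRegistry) -> UtilityIndex:
        return default_utility_index(registry)

    def cost_model(self) -> CostModel:
        return default_cost_model()

    def discount(self) -> DiscountSpec:
        return DiscountSpec(self.discount_rate)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("stages", "strategies", "bootstrap_outcomes", "fit_families"):
            d[key] = list(d[key])
        if d["cv_grid"] is not None:
            d["cv_grid"] = list(d["cv_grid"])
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(source: str | Path | dict | None = None, **overrides) -> RunConfig:
    """RunConfig from a YAML file or dict, with keyword overrides."""
    data: dict = {}
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        data = dict(source)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stages", "strategies", "bootstrap_outcomes", "cv_grid", "fit_families"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return RunConfig(**data)
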