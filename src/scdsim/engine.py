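"""Individual-based state-transition model with one-year cycles.

A simulated person occupies combinations of health states across four
parallel dimensions — chronic pain, acute events, chronic disorders, and
treatment complications — rather than one mutually exclusive state.  Each
annual cycle proceeds in a fixed order:

1. age advances and the current-year acute-event slate is cleared;
2. treatment use (hydroxyurea, acute/chronic transfusion) is drawn;
3. chronic and subacute incidence is drawn — chronic onsets are absorbing,
   subacute draws refresh the last-active year (a disorder stays "present"
   for two further years, mirroring the claims lookback), chronic pain is
   drawn every year in its own dimension;
4. acute events are drawn as instantaneous Bernoulli occurrences that leave
   only history counts behind;
5. treatment complications are drawn, conditioned on current treatments and
   on any attempted curative therapy;
6. utilization counts are drawn from log-link indices;
7. mortality is drawn from a background age/sex probability combined with
   per-attribute hazard ratios on the log-hazard scale.

Curative strategies are applied at model entry to eligible individuals
("severe" disease history): a responder draw with probability
``p_symptom_free`` decides whether the strategy's incidence risk ratios
apply; non-responders keep common-care dynamics but still face
attempted-therapy complications.  The death year is counted as a full
lived year (no half-cycle correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from scdsim import features
from scdsim.features import TREATMENT_FLAGS, UTILIZATION_CATEGORIES, feature_names
from scdsim.indices import PredictionIndex
from scdsim.registry import AttributeRegistry, Persistence
from scdsim.rng import spawn_children

__all__ = [
    "EligibilityRule",
    "TreatmentEffect",
    "Strategy",
    "MortalityModel",
    "PopulationSpec",
    "IndividualState",
    "SimulationModels",
    "YearRecord",
    "Trajectory",
    "CohortSummary",
    "check_eligibility",
    "advance_year",
    "simulate_lifetime",
    "run_cohort",
    "common_care",
]

SUBACUTE_LOOKBACK = 2  # years a subacute occurrence keeps the disorder present


@dataclass
class EligibilityRule:
    """Severity gate for curative therapy (history of severe adverse events).

    Default: lifetime count of severity-marked acute events at or above the
    threshold, or any stroke in history.
    """

    min_severe_events: int = 3
    stroke_qualifies: bool = True


@dataclass
class TreatmentEffect:
    p_symptom_free: float = 1.0
    risk_ratios: dict[str, float] = field(default_factory=dict)  # responders
    # complication -> (first-year probability, subsequent annual probability)
    complication_probabilities: dict[str, tuple[float, float]] = field(default_factory=dict)
    durability_half_life: float | None = None  # years; None = durable

    def __post_init__(self) -> None:
        for name, rr in self.risk_ratios.items():
            if rr < 0:
                raise ValueError(f"negative risk ratio for {name!r}")
        for name, (p0, p1) in self.complication_probabilities.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"complication probability for {name!r} outside [0, 1]")

    def risk_ratio_at(self, name: str, years_since: int) -> float:
        rr = self.risk_ratios.get(name, 1.0)
        if self.durability_half_life is not None and years_since > 0:
            # suppression wanes toward no effect with the configured half-life
            keep = 0.5 ** (years_since / self.durability_half_life)
            rr = 1.0 - (1.0 - rr) * keep
        return rr


def identity_effect() -> TreatmentEffect:
    return TreatmentEffect(p_symptom_free=1.0)


@dataclass
class Strategy:
    name: str
    effect: TreatmentEffect = field(default_factory=identity_effect)
    eligibility: EligibilityRule = field(default_factory=EligibilityRule)
    one_time_cost: float = 0.0
    therapy: str | None = None  # registry therapy key (complication set)

    def is_curative(self) -> bool:
        return self.name != "common_care"


def common_care() -> Strategy:
    return Strategy(name="common_care", one_time_cost=0.0)


@dataclass
class MortalityModel:
    """Annual death probability: background Gompertz times attribute hazards.

    ``q_bg(age) = a_sex * exp(b * age)``; active attributes multiply the
    log-hazard ``-log(1 - q_bg)`` by their hazard ratios, and the result is
    converted back to an annual probability clipped to [0, 1].
    """

    a_female: float = 2.4e-4
    a_male: float = 3.0e-4
    b: float = 0.08
    hazard_ratios: dict[str, float] = field(default_factory=dict)

    def background(self, age: float, sex_female: bool) -> float:
        a = self.a_female if sex_female else self.a_male
        return min(1.0, a * np.exp(self.b * age))

    def annual_probability(self, age, sex_female, active_names) -> float:
        q = min(self.background(age, sex_female), 1.0 - 1e-12)
        h = -np.log1p(-q)
        for name in active_names:
            h *= self.hazard_ratios.get(name, 1.0)
        return float(min(1.0, max(0.0, 1.0 - np.exp(-h))))


@dataclass
class PopulationSpec:
    """Initial-state distribution for simulated cohorts."""

    payer: str = "combined"
    age_mean: float = 27.8  # pooled public-payer cohorts
    age_sd: float = 18.0
    prop_female: float = 0.56
    entry_year: int = 2016
    prior_voe_rate: float = 0.15  # expected prior pain episodes per year of age
    horizon_age: int = 100


# ---------------------------------------------------------------------------
# compiled model bundle


class _CompiledFamily:
    def __init__(self, outcomes, names, indices):
        self.outcomes = list(outcomes)
        self.b = np.full(len(self.outcomes), -30.0)
        self.W = np.zeros((len(self.outcomes), len(names)))
        pos = {n: j for j, n in enumerate(names)}
        for i, out in enumerate(self.outcomes):
            ix = indices.get(out)
            if ix is None:
                continue
            self.b[i] = ix.intercept
            for name, w in ix.coefficients.items():
                if w != 0.0:
                    self.W[i, pos[name]] = w

    def linear(self, x: np.ndarray) -> np.ndarray:
        return self.b + self.W @ x


class SimulationModels:
    """Registry + compiled prediction indices + mortality model."""

    def __init__(
        self,
        registry: AttributeRegistry,
        indices: dict[str, PredictionIndex],
        mortality: MortalityModel | None = None,
    ):
        self.registry = registry
        self.indices = dict(indices)
        self.mortality = mortality or MortalityModel()

        self.dis_names = [a.name for a in registry.disease_attributes]
        self.comp_names = [a.name for a in registry.complication_attributes]
        dis_attrs = registry.disease_attributes
        self.acute_ix = np.array(
            [i for i, a in enumerate(dis_attrs) if a.persistence is Persistence.INSTANTANEOUS]
        )
        self.subacute_ix = np.array(
            [i for i, a in enumerate(dis_attrs) if a.persistence is Persistence.SUBACUTE]
        )
        self.chronic_ix = np.array(
            [i for i, a in enumerate(dis_attrs) if a.persistence is Persistence.CHRONIC]
        )
        self.persistent_ix = np.array(
            [i for i, a in enumerate(dis_attrs) if a.persistence is not Persistence.INSTANTANEOUS]
        )
        self.severity_ix = np.array(
            [i for i, a in enumerate(dis_attrs) if a.severity_marker]
        )
        self.stroke_i = self.dis_names.index("stroke") if "stroke" in self.dis_names else -1
        self.comp_chronic = np.array(
            [a.persistence is Persistence.CHRONIC for a in registry.complication_attributes]
        )
        # common-care therapy -> boolean mask over complication outcomes
        self.therapy_masks = {
            t: np.array([n in registry.therapy_complications.get(t, ()) for n in self.comp_names])
            for t in ("hydroxyurea", "transfusion")
        }
        self.mortality_hr = {
            "dis": np.array([self.mortality.hazard_ratios.get(n, 1.0) for n in self.dis_names]),
            "comp": np.array([self.mortality.hazard_ratios.get(n, 1.0) for n in self.comp_names]),
        }

        by_family: dict[str, dict[str, PredictionIndex]] = {}
        for ix in self.indices.values():
            by_family.setdefault(ix.family, {})[ix.outcome_name] = ix
        self.fam = {
            "incidence": _CompiledFamily(
                self.dis_names, feature_names("incidence", registry),
                by_family.get("incidence", {}),
            ),
            "treatment_use": _CompiledFamily(
                TREATMENT_FLAGS, feature_names("treatment_use", registry),
                by_family.get("treatment_use", {}),
            ),
            "complication": _CompiledFamily(
                self.comp_names, feature_names("complication", registry),
                by_family.get("complication", {}),
            ),
            "utilization": _CompiledFamily(
                UTILIZATION_CATEGORIES, feature_names("utilization", registry),
                by_family.get("utilization", {}),
            ),
        }

    def with_shifts(self, shifts: dict[str, float]) -> "SimulationModels":
        """Copy with incidence intercepts shifted (calibration)."""
        new_indices = dict(self.indices)
        for name, delta in shifts.items():
            key = name
            ix = new_indices.get(key)
            if ix is None or ix.family != "incidence":
                raise KeyError(f"no incidence index for {name!r}")
            new_indices[key] = ix.shifted(delta)
        return SimulationModels(self.registry, new_indices, self.mortality)


# ---------------------------------------------------------------------------
# individual state


class IndividualState:
    """One simulated person; array-backed for speed, dict views for reading."""

    __slots__ = (
        "models", "age", "sex_female", "birth_year", "payer", "alive",
        "year_index", "dis_flags", "prev_flags", "hist", "last_occurrence",
        "chronic_onset", "tx_flags", "prev_tx", "comp_flags", "prev_comp",
        "comp_onset", "comp_last_occ", "util", "cured", "strategy_received",
        "years_since_therapy", "acute_names_this_year",
    )

    def __init__(self, models: SimulationModels, age: float, sex_female: bool,
                 birth_year: int, payer: str = "combined"):
        n_dis = len(models.dis_names)
        n_comp = len(models.comp_names)
        self.models = models
        self.age = float(age)
        self.sex_female = bool(sex_female)
        self.birth_year = int(birth_year)
        self.payer = payer
        self.alive = True
        self.year_index = 0
        self.dis_flags = np.zeros(n_dis)
        self.prev_flags = np.zeros(n_dis)
        self.hist = np.zeros(n_dis)
        self.last_occurrence = np.full(n_dis, -10**6)  # subacute activity
        self.chronic_onset = np.full(n_dis, -1)
        self.tx_flags = np.zeros(3)
        self.prev_tx = np.zeros(3)
        self.comp_flags = np.zeros(n_comp)
        self.prev_comp = np.zeros(n_comp)
        self.comp_onset = np.full(n_comp, -1)
        self.comp_last_occ = np.full(n_comp, -10**6)
        self.util = np.zeros(3)
        self.cured = False
        self.strategy_received: str | None = None
        self.years_since_therapy = 0
        self.acute_names_this_year: tuple[str, ...] = ()

    # -- readable views -------------------------------------------------
    @property
    def chronic_pain(self) -> bool:
        i = self.models.dis_names.index("chronic_pain")
        return bool(self.dis_flags[i])

    @property
    def chronic_disorders(self) -> dict[str, int]:
        return {
            self.models.dis_names[i]: int(self.chronic_onset[i])
            for i in self.models.chronic_ix
            if self.chronic_onset[i] >= 0
        }

    @property
    def subacute_disorders(self) -> dict[str, int]:
        return {
            self.models.dis_names[i]: int(self.last_occurrence[i])
            for i in self.models.subacute_ix
            if self.last_occurrence[i] >= 0
        }

    @property
    def acute_event_history(self) -> dict[str, int]:
        return {
            self.models.dis_names[i]: int(self.hist[i])
            for i in self.models.acute_ix
            if self.hist[i] > 0
        }

    @property
    def treatments(self) -> dict[str, bool]:
        return dict(zip(TREATMENT_FLAGS, (bool(v) for v in self.tx_flags)))

    @property
    def complications(self) -> dict[str, int]:
        return {
            self.models.comp_names[j]: int(self.comp_onset[j])
            for j in range(len(self.models.comp_names))
            if self.comp_flags[j] > 0
        }


@dataclass
class YearRecord:
    year_index: int
    age: float
    dis_flags: np.ndarray
    comp_flags: np.ndarray
    tx_flags: np.ndarray
    util: np.ndarray
    acute_events: tuple[str, ...]
    died: bool


@dataclass
class Trajectory:
    sex_female: bool
    birth_year: int
    entry_age: float
    payer: str
    strategy: str
    strategy_received: str | None
    cured: bool
    one_time_cost: float
    records: list[YearRecord]

    @property
    def years_lived(self) -> int:
        return len(self.records)

    @property
    def died(self) -> bool:
        return bool(self.records) and self.records[-1].died


@dataclass
class CohortSummary:
    n: int
    person_years: int
    mean_survival: float
    lifetime_prevalence: dict[str, float]  # percent, disease + complications
    events_per_person_year: float


# ---------------------------------------------------------------------------
# cycle mechanics


def check_eligibility(state: IndividualState, rule: EligibilityRule) -> bool:
    """Severe-disease gate: enough severity-marked acute events, or a stroke."""
    if not state.alive:
        raise ValueError("eligibility is defined for living individuals")
    m = state.models
    severe = float(state.hist[m.severity_ix].sum()) if len(m.severity_ix) else 0.0
    if severe >= rule.min_severe_events:
        return True
    if rule.stroke_qualifies and m.stroke_i >= 0 and state.hist[m.stroke_i] > 0:
        return True
    return False


_N_DEMO = 1 + features.N_AGE_BANDS + len(features.COHORT_DECADES)


def _demo_vector(state: IndividualState) -> np.ndarray:
    # scalar fast path equivalent to features.demographic_vector
    v = np.zeros(_N_DEMO)
    v[0] = 1.0 if state.sex_female else 0.0
    band = min(max(int(state.age), 0), 99) // 5
    v[1 + band] = 1.0
    decade = min(max((state.birth_year // 10) * 10, 1920), 2010)
    v[1 + features.N_AGE_BANDS + (decade - 1920) // 10] = 1.0
    return v


def advance_year(
    state: IndividualState,
    rng: np.random.Generator,
    strategy_effect: TreatmentEffect | None = None,
    collect: bool = True,
    rng_util: np.random.Generator | None = None,
) -> YearRecord | None:
    """One annual cycle; mutates ``state`` and returns the year's record.

    ``rng`` drives all state transitions and consumes a fixed number of
    draws per cycle, so runs with perturbed parameters stay coupled under
    common random numbers (a small parameter change flips only marginal
    Bernoulli decisions).  Utilization counts are Poisson draws with
    data-dependent consumption; they do not feed back into the dynamics and
    are taken from ``rng_util`` when provided to preserve that coupling.
    """
    if not state.alive:
        raise ValueError("cannot advance a dead individual")
    m = state.models
    y = state.year_index + 1

    # (1) age, clear instantaneous events
    state.age += 1.0
    state.year_index = y
    flags = state.dis_flags
    flags[m.acute_ix] = 0.0
    # subacute presence decays after the lookback window
    sub = m.subacute_ix
    flags[sub] = (y - state.last_occurrence[sub] <= SUBACUTE_LOOKBACK) & (
        state.last_occurrence[sub] >= 0
    )
    csub = ~m.comp_chronic
    state.comp_flags[csub] = (y - state.comp_last_occ[csub] <= SUBACUTE_LOOKBACK) & (
        state.comp_last_occ[csub] >= 0
    )

    demo = _demo_vector(state)
    hist = np.minimum(state.hist, features.HISTORY_CAP)

    # (2) treatment use (suppressed for cured responders)
    x_tx = np.concatenate(
        (flags[m.persistent_ix], hist, state.prev_tx, state.prev_comp, demo)
    )
    p_tx = expit(m.fam["treatment_use"].linear(x_tx))
    if state.cured:
        p_tx = np.zeros_like(p_tx)
    state.tx_flags = (rng.random(3) < p_tx).astype(float)

    # (3)+(4) incidence of chronic/subacute disorders and acute events
    x_inc = np.concatenate(
        (state.prev_flags, hist, state.prev_tx, state.prev_comp, demo)
    )
    p_inc = expit(m.fam["incidence"].linear(x_inc))
    if state.cured and strategy_effect is not None:
        t = state.years_since_therapy
        rr = np.array(
            [strategy_effect.risk_ratio_at(n, t) for n in m.dis_names]
        )
        p_inc = p_inc * rr
        bad = p_inc > 1.0
        if bad.any():
            name = m.dis_names[int(np.argmax(bad))]
            raise ValueError(
                f"incidence probability for {name!r} exceeds 1 after risk ratio"
            )
    u = rng.random(len(p_inc))
    for i in m.chronic_ix:
        if flags[i] == 0.0 and u[i] < p_inc[i]:
            flags[i] = 1.0
            state.chronic_onset[i] = y
    for i in m.subacute_ix:
        if u[i] < p_inc[i]:
            flags[i] = 1.0
            state.last_occurrence[i] = y
    acute_hits = m.acute_ix[u[m.acute_ix] < p_inc[m.acute_ix]]
    flags[acute_hits] = 1.0
    state.acute_names_this_year = tuple(m.dis_names[i] for i in acute_hits)

    # (5) complications: common-care therapy sets via indices, attempted
    # curative therapy via configured probabilities
    x_comp = np.concatenate(
        (flags, state.tx_flags, hist, state.prev_comp, demo)
    )
    p_comp = expit(m.fam["complication"].linear(x_comp))
    allowed = np.zeros(len(m.comp_names), dtype=bool)
    if state.tx_flags[0] > 0:  # hydroxyurea
        allowed |= m.therapy_masks["hydroxyurea"]
    if state.tx_flags[1] > 0 or state.tx_flags[2] > 0:  # transfusion
        allowed |= m.therapy_masks["transfusion"]
    uc = rng.random(len(p_comp))
    for j in np.nonzero(allowed)[0]:
        if m.comp_chronic[j] and state.comp_flags[j] > 0:
            continue
        if uc[j] < p_comp[j]:
            state.comp_flags[j] = 1.0
            if m.comp_chronic[j]:
                if state.comp_onset[j] < 0:
                    state.comp_onset[j] = y
            state.comp_last_occ[j] = y
            if state.comp_onset[j] < 0:
                state.comp_onset[j] = y
    if state.strategy_received is not None and strategy_effect is not None:
        first = state.years_since_therapy == 0
        for name, (p0, p1) in strategy_effect.complication_probabilities.items():
            j = m.comp_names.index(name)
            if m.comp_chronic[j] and state.comp_flags[j] > 0:
                continue
            if rng.random() < (p0 if first else p1):
                state.comp_flags[j] = 1.0
                state.comp_last_occ[j] = y
                if state.comp_onset[j] < 0:
                    state.comp_onset[j] = y

    # (6) utilization
    x_util = np.concatenate(
        (flags, state.tx_flags, state.comp_flags, hist, demo)
    )
    rates = np.exp(np.minimum(m.fam["utilization"].linear(x_util), 6.0))
    state.util = (rng_util or rng).poisson(rates).astype(float)

    # (7) mortality: background log-hazard scaled by active-attribute HRs
    a = m.mortality.a_female if state.sex_female else m.mortality.a_male
    q_bg = min(a * math.exp(m.mortality.b * state.age), 1.0 - 1e-12)
    h = -math.log1p(-q_bg)
    h *= float(np.prod(m.mortality_hr["dis"][flags > 0]))
    h *= float(np.prod(m.mortality_hr["comp"][state.comp_flags > 0]))
    q = min(1.0, max(0.0, 1.0 - math.exp(-h)))
    died = bool(rng.random() < q)

    record = None
    if collect:
        record = YearRecord(
            year_index=y, age=state.age,
            dis_flags=flags.copy(), comp_flags=state.comp_flags.copy(),
            tx_flags=state.tx_flags.copy(), util=state.util.copy(),
            acute_events=state.acute_names_this_year, died=died,
        )

    # cycle end: promote current year to history
    state.hist += flags
    state.prev_flags = flags.copy()
    state.prev_tx = state.tx_flags.copy()
    state.prev_comp = state.comp_flags.copy()
    if state.strategy_received is not None:
        state.years_since_therapy += 1
    if died:
        state.alive = False
    return record


def simulate_lifetime(
    state: IndividualState,
    strategy: Strategy,
    rng: np.random.Generator,
    horizon_age: int = 100,
    collect: bool = True,
    rng_util: np.random.Generator | None = None,
) -> Trajectory:
    """Apply the strategy at entry (if eligible) and cycle until death/cap."""
    effect = None
    one_time_cost = 0.0
    if strategy.is_curative() and check_eligibility(state, strategy.eligibility):
        state.strategy_received = strategy.name
        state.cured = bool(rng.random() < strategy.effect.p_symptom_free)
        effect = strategy.effect
        one_time_cost = strategy.one_time_cost
    records = []
    while state.alive and state.age < horizon_age:
        rec = advance_year(state, rng, strategy_effect=effect, collect=collect,
                           rng_util=rng_util)
        if collect:
            records.append(rec)
    return Trajectory(
        sex_female=state.sex_female, birth_year=state.birth_year,
        entry_age=state.age - state.year_index, payer=state.payer,
        strategy=strategy.name, strategy_received=state.strategy_received,
        cured=state.cured, one_time_cost=one_time_cost, records=records,
    )


# ---------------------------------------------------------------------------
# cohorts


def sample_initial_state(
    models: SimulationModels, spec: PopulationSpec, rng: np.random.Generator
) -> IndividualState:
    shape = (spec.age_mean / spec.age_sd) ** 2
    scale = spec.age_sd**2 / spec.age_mean
    age = float(rng.gamma(shape, scale))
    sex_female = bool(rng.random() < spec.prop_female)
    state = IndividualState(
        models, age=age, sex_female=sex_female,
        birth_year=spec.entry_year - int(round(age)), payer=spec.payer,
    )
    if spec.prior_voe_rate > 0:
        i = models.dis_names.index("vaso_occlusive_pain_episodes")
        state.hist[i] = float(rng.poisson(spec.prior_voe_rate * age))
    return state


def run_cohort(
    n: int,
    spec: PopulationSpec,
    strategy: Strategy,
    models: SimulationModels,
    seed: int,
    collect: bool = False,
) -> tuple[list[Trajectory], CohortSummary]:
    """Simulate ``n`` independent lifetimes on per-individual substreams.

    Growing ``n`` with the same seed leaves earlier individuals unchanged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    children = spawn_children(np.random.SeedSequence([int(seed)]), n)
    trajectories: list[Trajectory] = []
    n_dis = len(models.dis_names)
    n_comp = len(models.comp_names)
    ever = np.zeros(n_dis)
    ever_comp = np.zeros(n_comp)
    total_years = 0
    total_events = 0.0
    for i in range(n):
        ss_main, ss_util = children[i].spawn(2)
        rng = np.random.default_rng(ss_main)
        rng_util = np.random.default_rng(ss_util)
        state = sample_initial_state(models, spec, rng)
        ever_i = np.zeros(n_dis)
        ever_c = np.zeros(n_comp)
        effect = None
        one_time_cost = 0.0
        if strategy.is_curative() and check_eligibility(state, strategy.eligibility):
            state.strategy_received = strategy.name
            state.cured = bool(rng.random() < strategy.effect.p_symptom_free)
            effect = strategy.effect
            one_time_cost = strategy.one_time_cost
        records = []
        while state.alive and state.age < spec.horizon_age:
            rec = advance_year(state, rng, strategy_effect=effect, collect=collect,
                               rng_util=rng_util)
            np.maximum(ever_i, state.prev_flags, out=ever_i)
            np.maximum(ever_c, state.prev_comp, out=ever_c)
            total_events += len(state.acute_names_this_year)
            if collect:
                records.append(rec)
        total_years += state.year_index
        ever += ever_i
        ever_comp += ever_c
        if collect:
            trajectories.append(Trajectory(
                sex_female=state.sex_female, birth_year=state.birth_year,
                entry_age=state.age - state.year_index, payer=state.payer,
                strategy=strategy.name, strategy_received=state.strategy_received,
                cured=state.cured, one_time_cost=one_time_cost, records=records,
            ))
    prevalence = {
        name: 100.0 * ever[i] / n for i, name in enumerate(models.dis_names)
    }
    prevalence.update(
        {name: 100.0 * ever_comp[j] / n for j, name in enumerate(models.comp_names)}
    )
    summary = CohortSummary(
        n=n,
        person_years=total_years,
        mean_survival=total_years / n,
        lifetime_prevalence=prevalence,
        events_per_person_year=total_events / max(total_years, 1),
    )
    return trajectories, summary
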