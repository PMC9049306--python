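"""Synthetic administrative-claims world for sickle cell disease cohorts.

Real Medicaid/Medicare/MarketScan claims are not redistributable, so this
module generates beneficiary populations whose *structure* matches what the
claims-analysis pipeline expects: enrollment spans at month granularity,
dated claims with positioned ICD-9/ICD-10 diagnosis codes (the coding system
switches editions at the October 2015 transition), procedure flags for
hydroxyurea, transfusion, and transplant, and death dates.

Scenario defaults reproduce the published cohort demographics (Medicaid mean
age at entry 16.9 years [SD 13.9], 53.4% female; Medicare 62.3 [16.2], 60.2%;
dual-eligible 33.3 [19.5], 58.1%).  Age at entry is drawn from a gamma
distribution matched to those moments, which keeps ages non-negative without
distorting the mean the way a truncated normal would.  Per-attribute annual
claim probabilities default to values consistent with published lifetime
prevalences over a nominal 25-year claims history.

Cohort-level moments are the only published constraints; the joint
correlation structure between attributes here (independent annual draws
given age) is a declared modeling choice.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from scdsim.registry import AttributeRegistry, default_registry
from scdsim.rng import substream

__all__ = [
    "ScenarioConfig",
    "ClaimsTables",
    "SchemaError",
    "scenario_config",
    "generate_population",
    "write_claims",
    "read_claims",
    "attribute_annual_probs_from_targets",
    "load_prevalence_targets",
    "BENEFICIARY_COLUMNS",
    "ENROLLMENT_COLUMNS",
    "CLAIM_COLUMNS",
]

BENEFICIARY_COLUMNS = ["beneficiary_id", "payer", "sex", "birth_year", "region", "death_year"]
ENROLLMENT_COLUMNS = ["beneficiary_id", "start_month", "end_month"]
CLAIM_COLUMNS = ["beneficiary_id", "service_date", "setting", "diagnoses", "procedures"]

SETTINGS = ("inpatient", "outpatient", "ED", "ambulatory")
REGIONS = ("northeast", "midwest", "south", "west")

# demographics printed for the three public-payer cohorts
_SCENARIO_DEMOGRAPHICS = {
    "medicaid": dict(age_mean=16.9, age_sd=13.9, prop_female=0.534),
    "medicare": dict(age_mean=62.3, age_sd=16.2, prop_female=0.602),
    "dual": dict(age_mean=33.3, age_sd=19.5, prop_female=0.581),
    "commercial": dict(age_mean=28.0, age_sd=16.0, prop_female=0.55),
}

# cohort sizes of the three public-payer cohorts, used as combined-scenario mix
_COHORT_WEIGHTS = {"medicaid": 39366, "medicare": 6522, "dual": 36846}

_ICD10_START = pd.Timestamp("2015-10-01")

# diagnosis codes that are deliberately outside every attribute/case code set
_NOISE_CODES = {
    "icd9": ("V70.0", "401.9", "272.4", "724.2", "462"),
    "icd10": ("Z00.00", "I10", "E78.5", "M54.50", "J02.9"),
}
_TRAIT_CODES = {"icd9": "282.5", "icd10": "D57.3"}
# non-crisis SCD codes: used on maintenance claims so that generic SCD care
# does not prefix-collide with the vaso-occlusive-episode attribute codes
_SCD_CODES = {"icd9": ("282.60", "282.61", "282.41", "282.42"), "icd10": ("D57.1", "D57.20", "D57.80", "D57.8")}


class SchemaError(ValueError):
    """A claims table does not conform to the documented CSV dialect."""


def load_prevalence_targets() -> pd.DataFrame:
    """Published lifetime-prevalence table (percent), indexed by attribute."""
    ref = resources.files("scdsim.data") / "prevalence_targets.csv"
    return pd.read_csv(io.StringIO(ref.read_text()), index_col="attribute")


def attribute_annual_probs_from_targets(
    column: str = "combined", horizon_years: float = 25.0
) -> dict[str, float]:
    """Annual claim probabilities consistent with lifetime prevalences.

    Solves 1-(1-p)^L = P for p with a nominal L-year claims history, per
    attribute.  Used as generator defaults so the synthetic claims world has
    realistic relative attribute frequencies.
    """
    targets = load_prevalence_targets()[column] / 100.0
    return {
        name: float(1.0 - (1.0 - P) ** (1.0 / horizon_years))
        for name, P in targets.items()
    }


@dataclass
class ScenarioConfig:
    """Generator parameters for one payer scenario."""

    payer: str = "medicaid"
    n_beneficiaries: int = 1000
    window: tuple[int, int] = (2008, 2016)
    age_mean: float = 16.9
    age_sd: float = 13.9
    prop_female: float = 0.534
    case_probability: float = 0.92
    # annual probability of >=1 qualifying claim, per disease attribute
    attribute_annual_probs: dict[str, float] = field(default_factory=dict)
    # optional log-odds slope per year of age relative to age 30
    attribute_age_slopes: dict[str, float] = field(default_factory=dict)
    complication_annual_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "hydroxyurea": {"leukopenia": 0.06, "thrombocytopenia": 0.05, "oligospermia_azospermia": 0.01},
            "transfusion": {"iron_overload": 0.10, "transfusion_reaction": 0.04, "transfusion_infection": 0.03},
        }
    )
    claims_per_event_extra: float = 0.4  # Poisson mean for repeat claims
    coding_noise_rate: float = 0.2  # extra irrelevant code on a claim
    scd_claims_per_year: float = 3.0  # SCD maintenance claims (cases)
    p_inpatient_index: float = 0.3
    noise_claims_per_year: float = 1.5  # non-case background claims
    trait_coder_rate: float = 0.05  # non-cases coded with trait only
    single_scd_claim_rate: float = 0.03  # non-cases with one outpatient SCD claim
    span_mean_months: float = 72.0
    span_min_months: int = 6
    gap_probability: float = 0.15
    p_hydroxyurea_user: float = 0.25
    p_chronic_transfusion_user: float = 0.08
    p_acute_transfusion_annual: float = 0.06
    hsct_annual_prob: float = 0.002
    mortality_a: float = 3.0e-4  # annual q = a * exp(b * age)
    mortality_b: float = 0.075
    seed: int = 0

    def validate(self) -> None:
        if self.n_beneficiaries < 1:
            raise ValueError("n_beneficiaries must be >= 1")
        if self.window[1] < self.window[0]:
            raise ValueError("empty study window")
        probs = [self.case_probability, self.prop_female, self.coding_noise_rate,
                 self.gap_probability, self.trait_coder_rate, self.single_scd_claim_rate,
                 *self.attribute_annual_probs.values()]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


def scenario_config(payer: str, n: int = 1000, seed: int = 0, **overrides) -> ScenarioConfig:
    """Default generator configuration for a named payer scenario."""
    if payer not in _SCENARIO_DEMOGRAPHICS:
        raise ValueError(f"unknown payer scenario {payer!r}")
    demo = _SCENARIO_DEMOGRAPHICS[payer]
    column = payer if payer in ("medicaid", "medicare", "dual") else "combined"
    cfg = ScenarioConfig(
        payer=payer,
        n_beneficiaries=n,
        attribute_annual_probs=attribute_annual_probs_from_targets(column),
        seed=seed,
        **demo,
    )
    return replace(cfg, **overrides)


def combined_scenario_configs(n_total: int, seed: int = 0) -> list[ScenarioConfig]:
    """Medicaid/Medicare/dual configs sized by the published cohort mix."""
    total_w = sum(_COHORT_WEIGHTS.values())
    configs = []
    for payer, w in _COHORT_WEIGHTS.items():
        n = max(1, round(n_total * w / total_w))
        configs.append(scenario_config(payer, n=n, seed=seed))
    return configs


@dataclass
class ClaimsTables:
    """The three claims-world tables (documented CSV dialects)."""

    beneficiaries: pd.DataFrame
    enrollment: pd.DataFrame
    claims: pd.DataFrame

    def validate(self) -> None:
        for df, cols, name in (
            (self.beneficiaries, BENEFICIARY_COLUMNS, "beneficiaries"),
            (self.enrollment, ENROLLMENT_COLUMNS, "enrollment"),
            (self.claims, CLAIM_COLUMNS, "claims"),
        ):
            for col in cols:
                if col not in df.columns:
                    raise SchemaError(f"{name} table missing column {col!r}")


# ---------------------------------------------------------------------------
# helpers


def _month_index(year: int, month: int) -> int:
    return year * 12 + (month - 1)


def _ym(mi: int) -> str:
    return f"{mi // 12:04d}-{mi % 12 + 1:02d}"


def _edition_for(date: pd.Timestamp) -> str:
    return "icd10" if date >= _ICD10_START else "icd9"


def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return shape, scale


def _serialize_dx(codes: list[tuple[str, str]]) -> str:
    return ";".join(f"{c}|{e}" for c, e in codes)


def parse_diagnoses(cell: str) -> list[tuple[str, str]]:
    """Parse the ``code|edition;...`` diagnosis column."""
    if not cell:
        return []
    out = []
    for tok in cell.split(";"):
        code, edition = tok.split("|")
        out.append((code, edition))
    return out


class _ClaimBuffer:
    def __init__(self) -> None:
        self.rows: list[tuple] = []

    def add(self, bid, date, setting, diagnoses, procedures=()):
        self.rows.append(
            (bid, date.date().isoformat(), setting, _serialize_dx(diagnoses), ";".join(procedures))
        )


def _random_day(rng, year: int, months: np.ndarray) -> pd.Timestamp:
    mi = int(months[rng.integers(len(months))])
    day = int(rng.integers(1, 29))
    return pd.Timestamp(year=mi // 12, month=mi % 12 + 1, day=day)


def _attr_code(rng, attr, edition: str) -> str:
    codes = sorted(attr.icd9_codes if edition == "icd9" else attr.icd10_codes)
    return codes[int(rng.integers(len(codes)))]


def _scd_code(rng, edition: str) -> str:
    pool = _SCD_CODES[edition]
    return pool[int(rng.integers(len(pool)))]


def _noise_code(rng, edition: str) -> str:
    pool = _NOISE_CODES[edition]
    return pool[int(rng.integers(len(pool)))]


def _with_noise(rng, codes: list[tuple[str, str]], edition: str, rate: float) -> list[tuple[str, str]]:
    if rate > 0 and rng.random() < rate:
        codes = codes + [(_noise_code(rng, edition), edition)]
    # shuffle so the informative code lands in a random claim position
    order = rng.permutation(len(codes))
    return [codes[i] for i in order]


# ---------------------------------------------------------------------------
# main generator


def generate_population(
    config: ScenarioConfig, registry: AttributeRegistry | None = None
) -> ClaimsTables:
    """Generate one payer scenario's beneficiaries, spans, and claims.

    Deterministic given ``config.seed``: the scenario draws from a named
    substream keyed on the payer, so multi-scenario runs are independent.
    """
    config.validate()
    registry = registry or default_registry()
    rng = substream(config.seed, "generate", config.payer)

    y0, y1 = config.window
    window_start = _month_index(y0, 1)
    window_end = _month_index(y1, 12)

    disease_attrs = registry.disease_attributes
    attr_p = np.array(
        [config.attribute_annual_probs.get(a.name, 0.0) for a in disease_attrs]
    )
    attr_slope = np.array(
        [config.attribute_age_slopes.get(a.name, 0.0) for a in disease_attrs]
    )
    with np.errstate(divide="ignore"):
        attr_logit = np.where(attr_p > 0, logit(np.clip(attr_p, 1e-12, 1 - 1e-12)), -np.inf)

    comp_attrs = {a.name: a for a in registry.complication_attributes}

    shape, scale = _gamma_params(config.age_mean, config.age_sd)

    bene_rows, span_rows = [], []
    claims = _ClaimBuffer()

    n = config.n_beneficiaries
    ages = rng.gamma(shape, scale, size=n)
    female = rng.random(n) < config.prop_female
    regions = rng.integers(0, len(REGIONS), size=n)
    is_case = rng.random(n) < config.case_probability
    entry_years = rng.integers(y0, y1 + 1, size=n)
    entry_months = rng.integers(1, 13, size=n)
    span_lengths = np.maximum(
        config.span_min_months, rng.exponential(config.span_mean_months, size=n)
    ).astype(int)
    hu_user = rng.random(n) < config.p_hydroxyurea_user
    ct_user = rng.random(n) < config.p_chronic_transfusion_user

    for i in range(n):
        bid = f"{config.payer}-{i:07d}"
        age0 = float(ages[i])
        entry_mi = _month_index(int(entry_years[i]), int(entry_months[i]))
        end_mi = min(entry_mi + int(span_lengths[i]) - 1, window_end)
        birth_year = int(entry_years[i]) - int(round(age0))

        # death process: annual probability a*exp(b*age) from entry onward
        death_year: int | None = None
        age = age0
        for year in range(int(entry_years[i]), y1 + 1):
            q = min(1.0, config.mortality_a * np.exp(config.mortality_b * age))
            if rng.random() < q:
                death_year = year
                break
            age += 1.0
        if death_year is not None:
            end_mi = min(end_mi, _month_index(death_year, 12))

        # enrollment spans: optionally split by a gap of 1-6 months
        spans: list[tuple[int, int]] = []
        if (
            config.gap_probability > 0
            and end_mi - entry_mi > 18
            and rng.random() < config.gap_probability
        ):
            cut = int(rng.integers(entry_mi + 6, end_mi - 8))
            gap = int(rng.integers(1, 7))
            spans = [(entry_mi, cut), (min(cut + gap + 1, end_mi), end_mi)]
            spans = [(a, b) for a, b in spans if b >= a]
        else:
            spans = [(entry_mi, end_mi)]

        bene_rows.append(
            (bid, config.payer, "female" if female[i] else "male", birth_year,
             REGIONS[regions[i]], death_year if death_year is not None else pd.NA)
        )
        for a, b in spans:
            span_rows.append((bid, _ym(a), _ym(b)))

        in_span_months: dict[int, np.ndarray] = {}
        for year in range(entry_mi // 12, end_mi // 12 + 1):
            months = [
                mi
                for mi in range(_month_index(year, 1), _month_index(year, 12) + 1)
                for a, b in spans
                if a <= mi <= b
            ]
            if months:
                in_span_months[year] = np.asarray(months)

        if not is_case[i]:
            # background noise claims; some beneficiaries code only the trait
            trait_only = rng.random() < config.trait_coder_rate
            lone_scd = (not trait_only) and rng.random() < config.single_scd_claim_rate
            for year, months in in_span_months.items():
                k = rng.poisson(config.noise_claims_per_year * len(months) / 12.0)
                for _ in range(k):
                    date = _random_day(rng, year, months)
                    ed = _edition_for(date)
                    code = _TRAIT_CODES[ed] if trait_only else _noise_code(rng, ed)
                    claims.add(bid, date, "outpatient", [(code, ed)])
            if lone_scd and in_span_months:
                year = min(in_span_months)
                date = _random_day(rng, year, in_span_months[year])
                ed = _edition_for(date)
                claims.add(bid, date, "outpatient", [(_scd_code(rng, ed), ed)])
            continue

        # ---- case beneficiary ----
        # index claim early in the first span
        first_span_start = spans[0][0]
        idx_mi = min(first_span_start + int(rng.integers(0, 3)), spans[0][1])
        idx_date = pd.Timestamp(year=idx_mi // 12, month=idx_mi % 12 + 1, day=int(rng.integers(1, 29)))
        ed = _edition_for(idx_date)
        setting = "inpatient" if rng.random() < config.p_inpatient_index else "outpatient"
        claims.add(
            bid, idx_date, setting,
            _with_noise(rng, [(_scd_code(rng, ed), ed)], ed, config.coding_noise_rate),
        )

        for year, months in in_span_months.items():
            frac = len(months) / 12.0
            age_y = year - birth_year
            # SCD maintenance claims satisfy the 2-outpatient case rule
            k = rng.poisson(config.scd_claims_per_year * frac)
            for _ in range(k):
                date = _random_day(rng, year, months)
                ed = _edition_for(date)
                s = ("outpatient", "ED", "ambulatory")[
                    int(rng.choice(3, p=[0.7, 0.2, 0.1]))
                ]
                claims.add(
                    bid, date, s,
                    _with_noise(rng, [(_scd_code(rng, ed), ed)], ed, config.coding_noise_rate),
                )

            # disease-attribute claims
            if attr_p.any():
                p_year = np.where(
                    np.isfinite(attr_logit),
                    expit(attr_logit + attr_slope * (age_y - 30.0)),
                    0.0,
                ) * frac
                hits = np.nonzero(rng.random(len(disease_attrs)) < p_year)[0]
                for j in hits:
                    attr = disease_attrs[j]
                    n_claims = 1 + rng.poisson(config.claims_per_event_extra)
                    for _ in range(n_claims):
                        date = _random_day(rng, year, months)
                        ed = _edition_for(date)
                        if attr.persistence.value == "instantaneous":
                            s = SETTINGS[int(rng.choice(4, p=[0.35, 0.25, 0.3, 0.1]))]
                        else:
                            s = SETTINGS[int(rng.choice(4, p=[0.1, 0.6, 0.1, 0.2]))]
                        codes = [(_attr_code(rng, attr, ed), ed)]
                        if rng.random() < 0.5:
                            codes.append((_scd_code(rng, ed), ed))
                        claims.add(bid, date, s, _with_noise(rng, codes, ed, config.coding_noise_rate))

            # treatment claims with procedure flags
            active_therapies = []
            if hu_user[i]:
                active_therapies.append("hydroxyurea")
            if ct_user[i]:
                active_therapies.append("transfusion")
            if hu_user[i] and rng.random() < frac:
                date = _random_day(rng, year, months)
                ed = _edition_for(date)
                claims.add(bid, date, "outpatient", [(_scd_code(rng, ed), ed)], ("hydroxyurea",))
            if ct_user[i] and rng.random() < frac:
                date = _random_day(rng, year, months)
                ed = _edition_for(date)
                claims.add(bid, date, "outpatient", [(_scd_code(rng, ed), ed)], ("chronic_transfusion",))
            if rng.random() < config.p_acute_transfusion_annual * frac:
                date = _random_day(rng, year, months)
                ed = _edition_for(date)
                claims.add(bid, date, "inpatient", [(_scd_code(rng, ed), ed)], ("acute_transfusion",))

            # treatment complications conditioned on therapy use
            for therapy in active_therapies:
                for comp_name, p in config.complication_annual_probs.get(therapy, {}).items():
                    if comp_name in comp_attrs and rng.random() < p * frac:
                        date = _random_day(rng, year, months)
                        ed = _edition_for(date)
                        claims.add(
                            bid, date, "outpatient",
                            [(_attr_code(rng, comp_attrs[comp_name], ed), ed)],
                        )

            # transplant
            if config.hsct_annual_prob > 0 and rng.random() < config.hsct_annual_prob * frac:
                date = _random_day(rng, year, months)
                ed = _edition_for(date)
                claims.add(bid, date, "inpatient", [(_scd_code(rng, ed), ed)], ("hsct",))

    beneficiaries = pd.DataFrame(bene_rows, columns=BENEFICIARY_COLUMNS)
    beneficiaries["death_year"] = beneficiaries["death_year"].astype("Int64")
    enrollment = pd.DataFrame(span_rows, columns=ENROLLMENT_COLUMNS)
    claims_df = pd.DataFrame(claims.rows, columns=CLAIM_COLUMNS)
    claims_df = claims_df.sort_values(
        ["beneficiary_id", "service_date", "setting", "diagnoses"], kind="mergesort"
    ).reset_index(drop=True)
    tables = ClaimsTables(beneficiaries, enrollment, claims_df)
    tables.validate()
    return tables


def concat_tables(parts: list[ClaimsTables]) -> ClaimsTables:
    """Concatenate scenario tables (e.g., the combined public-payer cohort)."""
    return ClaimsTables(
        beneficiaries=pd.concat([p.beneficiaries for p in parts], ignore_index=True),
        enrollment=pd.concat([p.enrollment for p in parts], ignore_index=True),
        claims=pd.concat([p.claims for p in parts], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# I/O: three CSVs with header rows, ISO dates, stable column order


def write_claims(tables: ClaimsTables, path: str | Path) -> None:
    tables.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tables.beneficiaries.to_csv(path / "beneficiaries.csv", index=False, columns=BENEFICIARY_COLUMNS)
    tables.enrollment.to_csv(path / "enrollment.csv", index=False, columns=ENROLLMENT_COLUMNS)
    tables.claims.to_csv(path / "claims.csv", index=False, columns=CLAIM_COLUMNS)


def read_claims(path: str | Path) -> ClaimsTables:
    path = Path(path)
    frames = {}
    for name, cols in (
        ("beneficiaries", BENEFICIARY_COLUMNS),
        ("enrollment", ENROLLMENT_COLUMNS),
        ("claims", CLAIM_COLUMNS),
    ):
        f = path / f"{name}.csv"
        if not f.exists():
            raise SchemaError(f"missing table file {f.name}")
        df = pd.read_csv(f, dtype=str, keep_default_na=False)
        for col in cols:
            if col not in df.columns:
                raise SchemaError(f"{name} table missing column {col!r}")
        frames[name] = df[cols]
    bene = frames["beneficiaries"]
    bene = bene.assign(
        birth_year=bene["birth_year"].astype(int),
        death_year=bene["death_year"].replace("", pd.NA).astype("Int64"),
    )
    return ClaimsTables(bene, frames["enrollment"], frames["claims"])
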