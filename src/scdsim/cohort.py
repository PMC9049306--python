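"""Claims-derived cohort construction and annual attribute panels.

Implements the claims-analysis procedure used to characterize the disease:

* case identification — one inpatient claim, or two outpatient/ED claims on
  distinct dates, carrying an SCD code in any diagnosis position (sickle
  cell trait codes never qualify);
* index date — the first SCD-coded utilization inside an enrollment span,
  treated as model entry;
* enrollment filtering — 12 months of continuous enrollment after index,
  and only the longest enrollment span per beneficiary contributes
  (ties break to the earliest span);
* censoring — follow-up ends at the earliest of death, disenrollment, the
  year preceding transplant, or the study window end;
* annual flags — acute events require a qualifying claim in the year,
  subacute disorders a claim within the current or two preceding years
  (a claim in the current year always makes a subacute disorder current),
  chronic disorders are present in every year from first diagnosis on;
* lifetime prevalence — the percent of beneficiaries ever flagged.

Partial first/last years count as whole panel years; the death year is
included as a final row, while the disenrollment year is excluded when the
span ends mid-year.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scdsim.registry import AttributeRegistry, Persistence, normalize_code
from scdsim.synthetic import ClaimsTables, parse_diagnoses

__all__ = [
    "CohortDefinition",
    "identify_cases",
    "compute_index_date",
    "build_panel",
    "lifetime_prevalence",
    "PanelResult",
    "TREATMENT_FLAGS",
]

TREATMENT_FLAGS = ("hydroxyurea", "acute_transfusion", "chronic_transfusion")
OUTPATIENT_LIKE = {"outpatient", "ED", "ambulatory"}


@dataclass
class CohortDefinition:
    payer: str | None = None  # restrict to one payer, or None for all
    window: tuple[int, int] = (2008, 2016)
    min_enrollment_months: int = 12

    def __post_init__(self) -> None:
        if self.window[1] < self.window[0]:
            raise ValueError("empty study window")


@dataclass
class PanelResult:
    panel: pd.DataFrame
    attrition: dict[str, int] = field(default_factory=dict)

    def __iter__(self):  # allow `panel, attrition = build_panel(...)` style
        yield self.panel
        yield self.attrition


# ---------------------------------------------------------------------------
# claim preprocessing


def _code_matcher(registry: AttributeRegistry):
    """Cached per-code lookups: SCD flag and matching attribute names."""

    prefix_maps = {"icd9": [], "icd10": []}
    for a in registry.attributes.values():
        for code in a.icd9_codes:
            prefix_maps["icd9"].append((normalize_code(code), a.name))
        for code in a.icd10_codes:
            prefix_maps["icd10"].append((normalize_code(code), a.name))

    @functools.lru_cache(maxsize=None)
    def match(code: str, edition: str) -> tuple[bool, tuple[str, ...]]:
        is_scd = registry.is_scd_code(code, edition)
        norm = normalize_code(code)
        attrs = tuple(
            name for prefix, name in prefix_maps[edition] if norm.startswith(prefix)
        )
        return is_scd, attrs

    return match


def _prepare_claims(claims: pd.DataFrame, registry: AttributeRegistry) -> pd.DataFrame:
    """Annotate raw claims with SCD flags, matched attributes, procedures."""
    match = _code_matcher(registry)
    is_scd_col, attrs_col, procs_col = [], [], []
    for dx_cell, proc_cell in zip(claims["diagnoses"], claims["procedures"].fillna("")):
        is_scd = False
        attrs: set[str] = set()
        for code, edition in parse_diagnoses(dx_cell):
            s, a = match(code, edition)
            is_scd = is_scd or s
            attrs.update(a)
        is_scd_col.append(is_scd)
        attrs_col.append(attrs)
        procs_col.append(set(proc_cell.split(";")) - {""} if proc_cell else set())
    out = claims.copy()
    out["date"] = pd.to_datetime(claims["service_date"])
    out["year"] = out["date"].dt.year
    out["month_index"] = out["year"] * 12 + out["date"].dt.month - 1
    out["is_scd"] = is_scd_col
    out["attrs"] = attrs_col
    out["procs"] = procs_col
    return out


def _span_frame(enrollment: pd.DataFrame) -> pd.DataFrame:
    start = pd.PeriodIndex(enrollment["start_month"], freq="M")
    end = pd.PeriodIndex(enrollment["end_month"], freq="M")
    df = enrollment.copy()
    df["start_mi"] = start.year * 12 + start.month - 1
    df["end_mi"] = end.year * 12 + end.month - 1
    if (df["end_mi"] < df["start_mi"]).any():
        raise ValueError("enrollment span with end before start")
    # overlapping spans for one beneficiary are malformed input
    df = df.sort_values(["beneficiary_id", "start_mi"])
    prev_end = df.groupby("beneficiary_id")["end_mi"].shift()
    if ((df["start_mi"] <= prev_end)).any():
        bad = df.loc[df["start_mi"] <= prev_end, "beneficiary_id"].iloc[0]
        raise ValueError(f"overlapping enrollment spans for beneficiary {bad!r}")
    return df


# ---------------------------------------------------------------------------
# operations


def identify_cases(
    claims: pd.DataFrame, registry: AttributeRegistry
) -> set[str]:
    """Beneficiaries meeting the claims case definition.

    One inpatient SCD-coded claim in any diagnosis position, or two
    outpatient/ED claims with SCD codes on distinct service dates.
    Ambulatory claims count with outpatient.  Trait-only coders never
    qualify because trait codes are excluded from the case definition.
    """
    if len(claims) == 0:
        return set()
    prepared = claims if "is_scd" in claims.columns else _prepare_claims(claims, registry)
    scd = prepared[prepared["is_scd"]]
    if len(scd) == 0:
        return set()
    inpatient = set(scd.loc[scd["setting"] == "inpatient", "beneficiary_id"])
    outp = scd[scd["setting"].isin(OUTPATIENT_LIKE)]
    counts = outp.groupby("beneficiary_id")["service_date"].nunique()
    two_outpatient = set(counts.index[counts >= 2])
    return inpatient | two_outpatient


def compute_index_date(
    bene_claims: pd.DataFrame,
    bene_spans: pd.DataFrame,
    registry: AttributeRegistry | None = None,
) -> pd.Timestamp:
    """Earliest SCD-coded claim date falling inside an enrollment span."""
    prepared = (
        bene_claims
        if "is_scd" in bene_claims.columns
        else _prepare_claims(bene_claims, registry)
    )
    spans = (
        bene_spans
        if "start_mi" in bene_spans.columns
        else _span_frame(bene_spans)
    )
    scd = prepared[prepared["is_scd"]]
    in_span = scd["month_index"].apply(
        lambda mi: bool(((spans["start_mi"] <= mi) & (mi <= spans["end_mi"])).any())
    )
    dates = scd.loc[in_span, "date"]
    if len(dates) == 0:
        raise ValueError("identified case has no SCD claim inside an enrollment span")
    return dates.min()


def _longest_span(spans: pd.DataFrame) -> pd.Series:
    lengths = spans["end_mi"] - spans["start_mi"]
    # longest span; ties break to the earliest start
    order = np.lexsort((spans["start_mi"].to_numpy(), -lengths.to_numpy()))
    return spans.iloc[order[0]]


def build_panel(
    tables: ClaimsTables,
    registry: AttributeRegistry,
    definition: CohortDefinition | None = None,
) -> PanelResult:
    """Annual person-year panel with attribute/treatment/utilization columns.

    Returns the panel plus an attrition table with counts dropped at each
    filter (case definition, in-span index, 12-month enrollment, censoring).
    """
    definition = definition or CohortDefinition()
    bene = tables.beneficiaries
    if definition.payer is not None:
        bene = bene[bene["payer"] == definition.payer]
    claims = tables.claims[tables.claims["beneficiary_id"].isin(bene["beneficiary_id"])]
    prepared = _prepare_claims(claims, registry)
    spans = _span_frame(tables.enrollment)

    attrition = {"beneficiaries": len(bene)}
    cases = identify_cases(prepared, registry)
    attrition["cases"] = len(cases)

    y0, y1 = definition.window
    disease = {a.name: a.persistence for a in registry.attributes.values()}
    attr_names = list(registry.attributes)

    bene_index = bene.set_index("beneficiary_id")
    claims_by_bene = dict(tuple(prepared.groupby("beneficiary_id")))
    spans_by_bene = dict(tuple(spans.groupby("beneficiary_id")))

    rows = []
    n_no_index = n_short_enroll = n_no_years = 0
    for bid in sorted(cases):
        bspans = spans_by_bene.get(bid)
        bclaims = claims_by_bene.get(bid)
        if bspans is None or bclaims is None:
            n_no_index += 1
            continue
        span = _longest_span(bspans)
        in_span = bclaims[
            (bclaims["month_index"] >= span["start_mi"])
            & (bclaims["month_index"] <= span["end_mi"])
        ]
        scd_dates = in_span.loc[in_span["is_scd"], "month_index"]
        if len(scd_dates) == 0:
            n_no_index += 1
            continue
        index_mi = int(scd_dates.min())
        index_year = index_mi // 12
        # continuous enrollment: the span must cover the N months post-index
        if span["end_mi"] - index_mi + 1 < definition.min_enrollment_months:
            n_short_enroll += 1
            continue

        info = bene_index.loc[bid]
        death_year = info["death_year"]
        has_death = pd.notna(death_year)

        span_end_year = span["end_mi"] // 12
        disenroll_year = (
            span_end_year if span["end_mi"] % 12 == 11 else span_end_year - 1
        )
        hsct_mis = [
            mi
            for mi, procs in zip(in_span["month_index"], in_span["procs"])
            if "hsct" in procs
        ]
        bounds = [(y1, "window_end"), (disenroll_year, "disenrollment")]
        if has_death:
            bounds.append((int(death_year), "death"))
        if hsct_mis:
            bounds.append((min(hsct_mis) // 12 - 1, "pre_hsct"))
        # earliest bound wins; on ties death > pre_hsct > window_end >
        # disenrollment (a span running through the window end is not a
        # disenrollment)
        priority = {"death": 0, "pre_hsct": 1, "window_end": 2, "disenrollment": 3}
        last_year, reason = min(bounds, key=lambda b: (b[0], priority[b[1]]))
        if last_year < index_year:
            n_no_years += 1
            continue

        # claim years per attribute (any setting, any position, within span)
        attr_years: dict[str, list[int]] = {}
        for year, attrs in zip(in_span["year"], in_span["attrs"]):
            for a in attrs:
                attr_years.setdefault(a, []).append(year)
        first_year = {a: min(ys) for a, ys in attr_years.items()}
        year_sets = {a: set(ys) for a, ys in attr_years.items()}

        tx_years = {t: set() for t in TREATMENT_FLAGS}
        for year, procs in zip(in_span["year"], in_span["procs"]):
            for t in TREATMENT_FLAGS:
                if t in procs:
                    tx_years[t].add(year)

        util = {
            "inpatient": in_span[in_span["setting"] == "inpatient"]
            .groupby("year")["service_date"].nunique(),
            "ed": in_span[in_span["setting"] == "ED"].groupby("year").size(),
            "outpatient": in_span[in_span["setting"].isin(["outpatient", "ambulatory"])]
            .groupby("year").size(),
        }

        birth_year = int(info["birth_year"])
        for year in range(index_year, last_year + 1):
            row = {
                "beneficiary_id": bid,
                "payer": info["payer"],
                "sex": info["sex"],
                "birth_year": birth_year,
                "year": year,
                "age": year - birth_year,
            }
            for a in attr_names:
                ys = year_sets.get(a)
                if not ys:
                    flag = False
                else:
                    p = disease[a]
                    if p is Persistence.INSTANTANEOUS:
                        flag = year in ys
                    elif p is Persistence.SUBACUTE:
                        flag = bool(ys & {year, year - 1, year - 2})
                    else:
                        flag = year >= first_year[a]
                row[f"attr_{a}"] = flag
            for t in TREATMENT_FLAGS:
                row[f"tx_{t}"] = year in tx_years[t]
            for u, series in util.items():
                row[f"util_{u}"] = int(series.get(year, 0))
            row["censored_reason"] = reason if year == last_year else ""
            rows.append(row)

    attrition["no_in_span_index"] = n_no_index
    attrition["short_enrollment"] = n_short_enroll
    attrition["censored_before_entry"] = n_no_years
    panel = pd.DataFrame(rows)
    attrition["included"] = panel["beneficiary_id"].nunique() if len(panel) else 0
    return PanelResult(panel, attrition)


def lifetime_prevalence(
    panel: pd.DataFrame, registry: AttributeRegistry
) -> pd.DataFrame:
    """Percent of beneficiaries ever flagged, per attribute and payer.

    The ``combined`` column pools all beneficiaries.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    attr_cols = [c for c in panel.columns if c.startswith("attr_")]
    ever = panel.groupby(["beneficiary_id", "payer"], sort=False)[attr_cols].any()
    payers = sorted(ever.index.get_level_values("payer").unique())
    out = {}
    for payer in payers:
        sub = ever.xs(payer, level="payer")
        out[payer] = sub.mean() * 100.0
    out["combined"] = ever.mean() * 100.0
    table = pd.DataFrame(out)
    table.index = [c[len("attr_"):] for c in table.index]
    table.index.name = "attribute"
    return table
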