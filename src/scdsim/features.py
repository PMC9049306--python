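"""Canonical covariate schema shared by index fitting and simulation.

Each prediction-index family has a fixed, ordered covariate layout.  The
same layout functions are used to build design matrices from claims-derived
panels and to assemble covariate vectors inside the simulation engine, so
fitted coefficients always line up with simulated states.

Blocks
------
* attribute flags — the 26 disease conditions in registry order, either for
  the previous year (incidence family) or the current year;
* persistent-status flags — the 13 subacute + chronic disorders only, used
  where current-year acute outcomes are not yet known at draw time;
* history — per-attribute count of prior flagged years (for chronic
  disorders this is the duration since onset in years);
* treatment and complication flags, previous or current year;
* demographics — sex, 5-year age-band indicators, birth-decade indicators.

Age enters as 5-year band indicators (0-4 through 95-99) and birth cohort
as decade indicators clamped to 1920-2010.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scdsim.registry import AttributeRegistry, Persistence

__all__ = [
    "FAMILIES",
    "UTILIZATION_CATEGORIES",
    "TREATMENT_FLAGS",
    "age_band_label",
    "cohort_label",
    "feature_names",
    "demographic_vector",
]

FAMILIES = ("incidence", "treatment_use", "complication", "utilization")
TREATMENT_FLAGS = ("hydroxyurea", "acute_transfusion", "chronic_transfusion")
UTILIZATION_CATEGORIES = ("inpatient", "ed", "outpatient")

N_AGE_BANDS = 20  # 5-year bands, 0-4 .. 95-99 (ages above clamp to the last)
COHORT_DECADES = tuple(range(1920, 2020, 10))

# History counts are capped at the claims-window scale (a study window is
# at most nine years, so fits never see larger values); the simulator caps
# its lifetime-accumulated counts identically, keeping covariates inside
# the support the coefficients were estimated on.
HISTORY_CAP = 8.0


def age_band_label(band: int) -> str:
    lo = band * 5
    return f"{lo:02d}_{lo + 4:02d}"


def age_band_of(age) -> np.ndarray:
    return np.clip(np.asarray(age, dtype=int), 0, 99) // 5


def cohort_label(decade: int) -> str:
    return str(decade)


def cohort_of(birth_year) -> np.ndarray:
    decade = (np.asarray(birth_year, dtype=int) // 10) * 10
    return np.clip(decade, COHORT_DECADES[0], COHORT_DECADES[-1])


# ---------------------------------------------------------------------------
# ordered name blocks


def disease_names(registry: AttributeRegistry) -> list[str]:
    return [a.name for a in registry.disease_attributes]


def persistent_names(registry: AttributeRegistry) -> list[str]:
    return [
        a.name
        for a in registry.disease_attributes
        if a.persistence is not Persistence.INSTANTANEOUS
    ]


def complication_names(registry: AttributeRegistry) -> list[str]:
    return [a.name for a in registry.complication_attributes]


def demographic_names() -> list[str]:
    return (
        ["sex_female"]
        + [f"age_band__{age_band_label(b)}" for b in range(N_AGE_BANDS)]
        + [f"cohort__{cohort_label(d)}" for d in COHORT_DECADES]
    )


def feature_names(family: str, registry: AttributeRegistry) -> list[str]:
    """The ordered covariate schema of one index family."""
    dis = disease_names(registry)
    comp = complication_names(registry)
    hist = [f"hist__{n}" for n in dis]
    demo = demographic_names()
    if family == "incidence":
        return (
            [f"prev__{n}" for n in dis]
            + hist
            + [f"prev_tx__{t}" for t in TREATMENT_FLAGS]
            + [f"prev_comp__{n}" for n in comp]
            + demo
        )
    if family == "treatment_use":
        return (
            [f"cur__{n}" for n in persistent_names(registry)]
            + hist
            + [f"prev_tx__{t}" for t in TREATMENT_FLAGS]
            + [f"prev_comp__{n}" for n in comp]
            + demo
        )
    if family == "complication":
        return (
            [f"cur__{n}" for n in dis]
            + [f"cur_tx__{t}" for t in TREATMENT_FLAGS]
            + hist
            + [f"prev_comp__{n}" for n in comp]
            + demo
        )
    if family == "utilization":
        return (
            [f"cur__{n}" for n in dis]
            + [f"cur_tx__{t}" for t in TREATMENT_FLAGS]
            + [f"cur_comp__{n}" for n in comp]
            + hist
            + demo
        )
    raise ValueError(f"unknown family {family!r}")


def demographic_vector(sex_female: bool, age: int, birth_year: int) -> np.ndarray:
    """Demographics block in the canonical order (length 1 + 20 + 10)."""
    v = np.zeros(1 + N_AGE_BANDS + len(COHORT_DECADES))
    v[0] = float(sex_female)
    v[1 + int(age_band_of(age))] = 1.0
    decade = int(cohort_of(birth_year))
    v[1 + N_AGE_BANDS + COHORT_DECADES.index(decade)] = 1.0
    return v


# ---------------------------------------------------------------------------
# panel-side block computation


def panel_blocks(panel: pd.DataFrame, registry: AttributeRegistry) -> pd.DataFrame:
    """Augment a sorted panel with prev-year, history, and demographic columns.

    History columns count prior flagged years (cumulative flag sum minus the
    current flag), which for absorbing chronic disorders equals the duration
    since onset.  Previous-year columns are valid only where the preceding
    row belongs to the same beneficiary and the immediately preceding year;
    the boolean ``has_lag`` column records that.
    """
    df = panel.sort_values(["beneficiary_id", "year"], kind="mergesort").reset_index(drop=True)
    all_attr = disease_names(registry) + complication_names(registry)
    flag_cols = [f"attr_{n}" for n in all_attr] + [f"tx_{t}" for t in TREATMENT_FLAGS]
    df[flag_cols] = df[flag_cols].astype(float)

    new: dict[str, np.ndarray] = {}
    g = df.groupby("beneficiary_id", sort=False)
    for n in disease_names(registry):
        col = f"attr_{n}"
        new[f"hist__{n}"] = np.minimum(
            (g[col].cumsum() - df[col]).to_numpy(), HISTORY_CAP
        )

    same_bene = df["beneficiary_id"].eq(df["beneficiary_id"].shift(1))
    consecutive = df["year"].eq(df["year"].shift(1) + 1)
    new["has_lag"] = (same_bene & consecutive).to_numpy()
    shifted = df[flag_cols].shift(1)
    for n in all_attr:
        new[f"prevflag__{n}"] = shifted[f"attr_{n}"].to_numpy()
    for t in TREATMENT_FLAGS:
        new[f"prevtx__{t}"] = shifted[f"tx_{t}"].to_numpy()

    new["sex_female"] = (df["sex"] == "female").to_numpy(dtype=float)
    bands = age_band_of(df["age"])
    for b in range(N_AGE_BANDS):
        new[f"age_band__{age_band_label(b)}"] = (bands == b).astype(float)
    decades = cohort_of(df["birth_year"])
    for d in COHORT_DECADES:
        new[f"cohort__{cohort_label(d)}"] = (decades == d).astype(float)
    return pd.concat([df, pd.DataFrame(new, index=df.index)], axis=1)


def design_columns(
    blocks: pd.DataFrame, family: str, registry: AttributeRegistry
) -> pd.DataFrame:
    """Extract the family's covariates (canonical names/order) from blocks."""
    names = feature_names(family, registry)
    out = {}
    for name in names:
        if name.startswith("prev__"):
            out[name] = blocks[f"prevflag__{name[len('prev__'):]}"]
        elif name.startswith("prev_comp__"):
            out[name] = blocks[f"prevflag__{name[len('prev_comp__'):]}"]
        elif name.startswith("prev_tx__"):
            out[name] = blocks[f"prevtx__{name[len('prev_tx__'):]}"]
        elif name.startswith("cur_tx__"):
            out[name] = blocks[f"tx_{name[len('cur_tx__'):]}"]
        elif name.startswith("cur_comp__"):
            out[name] = blocks[f"attr_{name[len('cur_comp__'):]}"]
        elif name.startswith("cur__"):
            out[name] = blocks[f"attr_{name[len('cur__'):]}"]
        else:  # hist__ and demographics exist under their canonical names
            out[name] = blocks[name]
    return pd.DataFrame(out, index=blocks.index)
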