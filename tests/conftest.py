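import pandas as pd
import pytest

from scdsim.registry import default_registry
from scdsim.synthetic import (
    BENEFICIARY_COLUMNS,
    CLAIM_COLUMNS,
    ENROLLMENT_COLUMNS,
    ClaimsTables,
    generate_population,
    scenario_config,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_tables(registry):
    """A 200-beneficiary synthetic claims world with gaps, deaths, and HSCT."""
    cfg = scenario_config(
        "medicaid",
        n=200,
        seed=42,
        hsct_annual_prob=0.03,
        gap_probability=0.3,
        mortality_a=2e-3,
    )
    return generate_population(cfg, registry)


def make_claim(bid, date, setting, codes, procs=()):
    """One claims-table row from (code, edition) pairs."""
    return {
        "beneficiary_id": bid,
        "service_date": date,
        "setting": setting,
        "diagnoses": ";".join(f"{c}|{e}" for c, e in codes),
        "procedures": ";".join(procs),
    }


def tables_from_rows(bene_rows, span_rows, claim_rows):
    bene = pd.DataFrame(bene_rows, columns=BENEFICIARY_COLUMNS)
    bene["death_year"] = bene["death_year"].astype("Int64")
    return ClaimsTables(
        beneficiaries=bene,
        enrollment=pd.DataFrame(span_rows, columns=ENROLLMENT_COLUMNS),
        claims=pd.DataFrame(claim_rows, columns=CLAIM_COLUMNS),
    )
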