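"""Cohort derivation: case definition, index, censoring, panel semantics.

The panel construction is cross-checked against an independent brute-force
oracle written as plain nested loops over claims and spans.
"""

import numpy as np
import pandas as pd
import pytest

from scdsim.cohort import (
    build_panel,
    compute_index_date,
    identify_cases,
    lifetime_prevalence,
)
from scdsim.registry import Persistence

from conftest import make_claim, tables_from_rows


def bene_row(bid, payer="medicaid", sex="female", birth_year=2000, death=pd.NA):
    return (bid, payer, sex, birth_year, "south", death)


# ---------------------------------------------------------------------------
# brute-force oracle (independent nested-loop implementation)


def oracle_panel(tables, registry, window=(2008, 2016), min_months=12):
    """Recompute panel flags with naive loops; returns {(bid, year): row}."""

    def month_idx(ym):
        y, m = ym.split("-")
        return int(y) * 12 + int(m) - 1

    claims = []
    for _, c in tables.claims.iterrows():
        codes = [tuple(tok.split("|")) for tok in c["diagnoses"].split(";") if tok]
        procs = set(str(c["procedures"]).split(";")) - {"", "nan"}
        y, m, d = (int(x) for x in c["service_date"].split("-"))
        claims.append(
            dict(bid=c["beneficiary_id"], year=y, mi=y * 12 + m - 1,
                 date=c["service_date"], setting=c["setting"], codes=codes,
                 procs=procs)
        )

    spans = {}
    for _, s in tables.enrollment.iterrows():
        spans.setdefault(s["beneficiary_id"], []).append(
            (month_idx(s["start_month"]), month_idx(s["end_month"]))
        )

    out = {}
    for _, b in tables.beneficiaries.iterrows():
        bid = b["beneficiary_id"]
        mine = [c for c in claims if c["bid"] == bid]
        scd = [
            c for c in mine
            if any(registry.is_scd_code(code, ed) for code, ed in c["codes"])
        ]
        inpat = [c for c in scd if c["setting"] == "inpatient"]
        outp_dates = {c["date"] for c in scd if c["setting"] in ("outpatient", "ED", "ambulatory")}
        if not (len(inpat) >= 1 or len(outp_dates) >= 2):
            continue
        bspans = sorted(spans.get(bid, []), key=lambda s: (-(s[1] - s[0]), s[0]))
        if not bspans:
            continue
        lo, hi = bspans[0]
        in_span = [c for c in mine if lo <= c["mi"] <= hi]
        scd_in = sorted(c["mi"] for c in in_span
                        if any(registry.is_scd_code(code, ed) for code, ed in c["codes"]))
        if not scd_in:
            continue
        index_mi = scd_in[0]
        if hi - index_mi + 1 < min_months:
            continue
        index_year = index_mi // 12
        stop = window[1]
        reason = "window_end"
        dis_year = hi // 12 if hi % 12 == 11 else hi // 12 - 1
        if dis_year < stop:
            stop, reason = dis_year, "disenrollment"
        hsct = sorted(c["mi"] for c in in_span if "hsct" in c["procs"])
        if hsct and hsct[0] // 12 - 1 <= stop:
            stop, reason = hsct[0] // 12 - 1, "pre_hsct"
        if pd.notna(b["death_year"]) and int(b["death_year"]) <= stop:
            stop, reason = int(b["death_year"]), "death"
        if stop < index_year:
            continue
        for year in range(index_year, stop + 1):
            flags = {}
            for a in registry.attributes.values():
                years = set()
                for c in in_span:
                    for code, ed in c["codes"]:
                        if a.matches(code, ed):
                            years.add(c["year"])
                if a.persistence is Persistence.INSTANTANEOUS:
                    flag = year in years
                elif a.persistence is Persistence.SUBACUTE:
                    flag = bool(years & {year, year - 1, year - 2})
                else:
                    flag = bool(years) and year >= min(years)
                flags[a.name] = flag
            out[(bid, year)] = dict(
                flags=flags, last=(year == stop), reason=reason
            )
    return out


# ---------------------------------------------------------------------------


class TestCaseIdentification:
    def test_one_inpatient_claim_any_position(self, registry):
        rows = [make_claim("b1", "2010-05-01", "inpatient",
                           [("401.9", "icd9"), ("272.4", "icd9"), ("D57.0", "icd10")])]
        assert identify_cases(pd.DataFrame(rows), registry) == {"b1"}

    def test_single_outpatient_claim_is_not_a_case(self, registry):
        rows = [make_claim("b1", "2010-05-01", "outpatient", [("D57.1", "icd10")])]
        assert identify_cases(pd.DataFrame(rows), registry) == set()

    def test_two_trait_only_ed_claims_are_not_a_case(self, registry):
        rows = [
            make_claim("b1", "2010-05-01", "ED", [("282.5", "icd9")]),
            make_claim("b1", "2010-07-01", "ED", [("282.5", "icd9")]),
        ]
        assert identify_cases(pd.DataFrame(rows), registry) == set()

    def test_two_outpatient_distinct_dates(self, registry):
        rows = [
            make_claim("b1", "2010-05-01", "outpatient", [("D57.1", "icd10")]),
            make_claim("b1", "2010-06-01", "ED", [("282.62", "icd9")]),
            # same-date pair does not qualify
            make_claim("b2", "2010-05-01", "outpatient", [("D57.1", "icd10")]),
            make_claim("b2", "2010-05-01", "ED", [("D57.1", "icd10")]),
        ]
        assert identify_cases(pd.DataFrame(rows), registry) == {"b1"}

    def test_empty_input(self, registry):
        assert identify_cases(pd.DataFrame(columns=["beneficiary_id"]), registry) == set()


class TestIndexDate:
    spans = pd.DataFrame(
        [("b1", "2009-01", "2012-12")],
        columns=["beneficiary_id", "start_month", "end_month"],
    )

    def test_earliest_scd_claim_not_earliest_claim(self, registry):
        claims = pd.DataFrame([
            make_claim("b1", "2009-01-15", "outpatient", [("401.9", "icd9")]),
            make_claim("b1", "2010-05-01", "outpatient", [("282.62", "icd9")]),
        ])
        assert compute_index_date(claims, self.spans, registry) == pd.Timestamp("2010-05-01")

    def test_setting_irrelevant_on_tied_dates(self, registry):
        claims = pd.DataFrame([
            make_claim("b1", "2010-05-01", "inpatient", [("282.62", "icd9")]),
            make_claim("b1", "2010-05-01", "ED", [("D57.1", "icd10")]),
        ])
        assert compute_index_date(claims, self.spans, registry) == pd.Timestamp("2010-05-01")

    def test_out_of_span_claim_skipped(self, registry):
        claims = pd.DataFrame([
            make_claim("b1", "2008-03-01", "outpatient", [("282.62", "icd9")]),
            make_claim("b1", "2010-05-01", "outpatient", [("282.62", "icd9")]),
        ])
        assert compute_index_date(claims, self.spans, registry) == pd.Timestamp("2010-05-01")

    def test_no_in_span_claim_raises(self, registry):
        claims = pd.DataFrame([
            make_claim("b1", "2008-03-01", "outpatient", [("282.62", "icd9")]),
        ])
        with pytest.raises(ValueError):
            compute_index_date(claims, self.spans, registry)


def two_scd_claims(bid, d1, d2):
    return [
        make_claim(bid, d1, "outpatient", [("D57.1", "icd10")]),
        make_claim(bid, d2, "outpatient", [("D57.1", "icd10")]),
    ]


class TestPanelSemantics:
    def build(self, registry, claim_rows, death=pd.NA, span=("2009-01", "2016-12")):
        tables = tables_from_rows(
            [bene_row("b1", death=death)],
            [("b1", *span)],
            claim_rows,
        )
        return build_panel(tables, registry).panel

    def test_subacute_two_year_lookback(self, registry):
        rows = two_scd_claims("b1", "2009-02-01", "2009-03-01")
        rows.append(make_claim("b1", "2010-06-01", "outpatient", [("G89.29", "icd10")]))
        panel = self.build(registry, rows).set_index("year")
        assert panel.loc[2010, "attr_chronic_pain"]
        assert panel.loc[2011, "attr_chronic_pain"]
        assert panel.loc[2012, "attr_chronic_pain"]
        assert not panel.loc[2013, "attr_chronic_pain"]

    def test_chronic_flag_absorbing(self, registry):
        rows = two_scd_claims("b1", "2009-02-01", "2009-03-01")
        rows.append(make_claim("b1", "2011-06-01", "outpatient", [("585.9", "icd9")]))
        panel = self.build(registry, rows).set_index("year")
        assert not panel.loc[2010, "attr_chronic_renal_disease"]
        assert panel.loc[2011:, "attr_chronic_renal_disease"].all()

    def test_hsct_censors_at_preceding_year(self, registry):
        rows = two_scd_claims("b1", "2009-02-01", "2009-03-01")
        rows.append(make_claim("b1", "2014-06-01", "inpatient",
                               [("D57.1", "icd10")], procs=("hsct",)))
        panel = self.build(registry, rows)
        assert panel["year"].max() == 2013
        assert panel.iloc[-1]["censored_reason"] == "pre_hsct"

    def test_death_year_is_final_row(self, registry):
        rows = two_scd_claims("b1", "2009-02-01", "2009-03-01")
        panel = self.build(registry, rows, death=2012)
        assert panel["year"].max() == 2012
        assert panel.iloc[-1]["censored_reason"] == "death"

    def test_mid_year_disenrollment_excludes_final_year(self, registry):
        rows = two_scd_claims("b1", "2009-02-01", "2009-03-01")
        panel = self.build(registry, rows, span=("2009-01", "2013-06"))
        assert panel["year"].max() == 2012
        assert panel.iloc[-1]["censored_reason"] == "disenrollment"

    def test_short_enrollment_dropped(self, registry):
        rows = two_scd_claims("b1", "2009-02-01", "2009-03-01")
        panel = self.build(registry, rows, span=("2009-01", "2009-10"))
        assert len(panel) == 0

    def test_years_consecutive_and_chronic_monotone(self, registry, small_tables):
        panel = build_panel(small_tables, registry).panel
        chronic_cols = [
            f"attr_{a.name}" for a in registry.attributes.values()
            if a.persistence is Persistence.CHRONIC
        ]
        for _, g in panel.groupby("beneficiary_id"):
            years = g["year"].to_numpy()
            assert (np.diff(years) == 1).all()
            for col in chronic_cols:
                v = g[col].to_numpy().astype(int)
                assert (np.diff(v) >= 0).all()


class TestOracleEquivalence:
    def test_panel_matches_brute_force(self, registry, small_tables):
        panel = build_panel(small_tables, registry).panel
        expected = oracle_panel(small_tables, registry)
        got_keys = set(zip(panel["beneficiary_id"], panel["year"]))
        assert got_keys == set(expected)
        for _, row in panel.iterrows():
            exp = expected[(row["beneficiary_id"], row["year"])]
            for name, flag in exp["flags"].items():
                assert bool(row[f"attr_{name}"]) == flag, (
                    row["beneficiary_id"], row["year"], name
                )
            if exp["last"]:
                assert row["censored_reason"] == exp["reason"]
            else:
                assert row["censored_reason"] == ""


class TestLifetimePrevalence:
    def test_direct_count(self, registry):
        rows = []
        bene, spans = [], []
        for i in range(4):
            bid = f"b{i}"
            bene.append(bene_row(bid))
            spans.append((bid, "2009-01", "2016-12"))
            rows += two_scd_claims(bid, "2009-02-01", "2009-03-01")
        # 2 of 4 ever have a stroke claim
        rows.append(make_claim("b0", "2010-01-01", "inpatient", [("434.91", "icd9")]))
        rows.append(make_claim("b1", "2012-01-01", "ED", [("I63.9", "icd10")]))
        tables = tables_from_rows(bene, spans, rows)
        panel = build_panel(tables, registry).panel
        prev = lifetime_prevalence(panel, registry)
        assert prev.loc["stroke", "combined"] == 50.0
        assert prev.loc["leg_ulcers", "combined"] == 0.0

    def test_matches_per_person_scan_and_is_order_invariant(
        self, registry, small_tables
    ):
        panel = build_panel(small_tables, registry).panel
        prev = lifetime_prevalence(panel, registry)
        # independent per-person scan
        for name in ("stroke", "asthma", "chronic_renal_disease", "chronic_pain"):
            ever = 0
            bids = panel["beneficiary_id"].unique()
            for bid in bids:
                sub = panel[panel["beneficiary_id"] == bid]
                ever += int(sub[f"attr_{name}"].any())
            assert prev.loc[name, "combined"] == pytest.approx(100.0 * ever / len(bids))
        shuffled = panel.sample(frac=1.0, random_state=0)
        prev2 = lifetime_prevalence(shuffled, registry)
        pd.testing.assert_frame_equal(
            prev.sort_index(), prev2.sort_index(), check_like=True
        )

    def test_dropping_all_claims_of_attribute_zeroes_prevalence(
        self, registry, small_tables
    ):
        keep = []
        for _, c in small_tables.claims.iterrows():
            codes = [tok.split("|")[0] for tok in c["diagnoses"].split(";") if tok]
            if not any(code in ("493.90", "J45.909") for code in codes):
                keep.append(c)
        tables = tables_from_rows(
            small_tables.beneficiaries.values.tolist(),
            small_tables.enrollment.values.tolist(),
            [dict(c) for c in keep],
        )
        panel = build_panel(tables, registry).panel
        prev = lifetime_prevalence(panel, registry)
        assert prev.loc["asthma", "combined"] == 0.0
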