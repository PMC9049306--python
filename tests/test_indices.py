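"""Prediction indices: splits, design contracts, penalized fits, bootstrap."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from scdsim.features import TREATMENT_FLAGS, feature_names
from scdsim.indices import (
    Design,
    PenaltySpec,
    SplitSpec,
    bootstrap_uncertainty,
    build_design,
    fit_index,
    predict_probability,
    split_sample,
)
from scdsim.registry import Persistence


# ---------------------------------------------------------------------------
# panel fixtures


def toy_panel(registry, rows):
    """Panel from (bid, year, {attr: flag}, {tx: flag}) tuples."""
    out = []
    for bid, year, attrs, txs in rows:
        row = {
            "beneficiary_id": bid, "payer": "medicaid", "sex": "female",
            "birth_year": 1990, "year": year, "age": year - 1990,
        }
        for a in registry.attributes:
            row[f"attr_{a}"] = bool(attrs.get(a, False))
        for t in TREATMENT_FLAGS:
            row[f"tx_{t}"] = bool(txs.get(t, False))
        for u in ("inpatient", "ed", "outpatient"):
            row[f"util_{u}"] = attrs.get(f"util_{u}", 0)
        row["censored_reason"] = ""
        out.append(row)
    return pd.DataFrame(out)


@pytest.fixture(scope="module")
def random_panel(registry):
    """A 50-person random panel for design-oracle comparison."""
    rng = np.random.default_rng(99)
    rows = []
    for i in range(50):
        n_years = rng.integers(1, 6)
        start = int(rng.integers(2008, 2012))
        for year in range(start, start + n_years):
            attrs = {
                a.name: bool(rng.random() < 0.15)
                for a in registry.attributes.values()
            }
            txs = {t: bool(rng.random() < 0.2) for t in TREATMENT_FLAGS}
            rows.append((f"p{i}", year, attrs, txs))
    panel = toy_panel(registry, rows)
    # enforce chronic monotonicity like a real panel
    chronic = [a.name for a in registry.attributes.values()
               if a.persistence is Persistence.CHRONIC]
    for name in chronic:
        col = f"attr_{name}"
        panel[col] = panel.groupby("beneficiary_id")[col].cummax()
    return panel


# ---------------------------------------------------------------------------


class TestSplitSample:
    def test_100_beneficiaries_split_50_25_25(self, registry):
        rows = [(f"b{i}", 2010, {}, {}) for i in range(100)]
        panel = toy_panel(registry, rows)
        parts = split_sample(panel, SplitSpec(seed=1))
        assert [p["beneficiary_id"].nunique() for p in parts] == [50, 25, 25]

    def test_same_seed_identical_partition(self, registry):
        rows = [(f"b{i}", 2010, {}, {}) for i in range(37)]
        panel = toy_panel(registry, rows)
        a = split_sample(panel, SplitSpec(seed=5))
        b = split_sample(panel, SplitSpec(seed=5))
        for x, y in zip(a, b):
            assert set(x["beneficiary_id"]) == set(y["beneficiary_id"])

    def test_beneficiary_level_partition(self, registry):
        rows = []
        for i in range(20):
            for year in (2010, 2011, 2012):
                rows.append((f"b{i}", year, {}, {}))
        panel = toy_panel(registry, rows)
        parts = split_sample(panel, SplitSpec(seed=2))
        sets = [set(p["beneficiary_id"]) for p in parts]
        assert sets[0] | sets[1] | sets[2] == {f"b{i}" for i in range(20)}
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
        # every person-year of a beneficiary lands in exactly one part
        assert sum(len(p) for p in parts) == len(panel)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.3, 0.3))


class TestBuildDesign:
    def test_lag_requirement(self, registry):
        panel = toy_panel(registry, [
            ("b1", 2010, {}, {}), ("b1", 2011, {}, {}), ("b1", 2012, {}, {}),
        ])
        d = build_design(panel, "stroke", "incidence", registry)
        assert sorted(d.X.index.map(lambda i: panel.loc[i, "year"])) == [2011, 2012]

    def test_absorbing_outcome_excluded_once_present(self, registry):
        rows = [("b1", y, {"chronic_renal_disease": y >= 2011}, {})
                for y in range(2010, 2014)]
        panel = toy_panel(registry, rows)
        d = build_design(panel, "chronic_renal_disease", "incidence", registry)
        years = sorted(panel.loc[d.X.index, "year"])
        assert years == [2011]  # 2010 lacks lag; 2012+ already present
        assert d.y.tolist() == [1]

    def test_family_outcome_mismatch_rejected(self, registry, random_panel):
        with pytest.raises(ValueError):
            build_design(random_panel, "inpatient", "incidence", registry)
        with pytest.raises(ValueError):
            build_design(random_panel, "stroke", "utilization", registry)
        with pytest.raises(ValueError):
            build_design(random_panel, "nonexistent", "incidence", registry)

    def test_design_matches_hand_coded_oracle(self, registry, random_panel):
        """Row-for-row check of the incidence design on a 50-person panel."""
        d = build_design(random_panel, "asthma", "incidence", registry)
        panel = random_panel.sort_values(["beneficiary_id", "year"]).reset_index(drop=True)
        # independent nested-loop construction
        expected_rows = {}
        for bid, sub in panel.groupby("beneficiary_id"):
            sub = sub.sort_values("year")
            years = sub["year"].tolist()
            for k, year in enumerate(years):
                if k == 0 or years[k - 1] != year - 1:
                    continue
                prev = sub.iloc[k - 1]
                row = {}
                for a in registry.disease_attributes:
                    row[f"prev__{a.name}"] = float(prev[f"attr_{a.name}"])
                for a in registry.disease_attributes:
                    row[f"hist__{a.name}"] = float(
                        sum(sub.iloc[j][f"attr_{a.name}"] for j in range(k))
                    )
                for t in TREATMENT_FLAGS:
                    row[f"prev_tx__{t}"] = float(prev[f"tx_{t}"])
                for a in registry.complication_attributes:
                    row[f"prev_comp__{a.name}"] = float(prev[f"attr_{a.name}"])
                row["sex_female"] = 1.0
                age = year - 1990
                row[f"age_band__{age // 5 * 5:02d}_{age // 5 * 5 + 4:02d}"] = 1.0
                row["cohort__1990"] = 1.0
                expected_rows[(bid, year)] = (row, int(sub.iloc[k]["attr_asthma"]))
        assert len(d) == len(expected_rows)
        got = d.X.copy()
        got["bid"] = d.groups.to_numpy()
        got["year"] = [
            int(yv) for yv in random_panel.sort_values(
                ["beneficiary_id", "year"]
            ).reset_index(drop=True).loc[got.index, "year"]
        ]
        for _, row in got.iterrows():
            exp, _ = expected_rows[(row["bid"], row["year"])]
            for name in feature_names("incidence", registry):
                assert row[name] == exp.get(name, 0.0), (row["bid"], row["year"], name)


def simulate_logistic(n, beta, intercept, seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(beta)))
    p = expit(intercept + X @ beta)
    y = (rng.random(n) < p).astype(int)
    names = [f"x{i}" for i in range(len(beta))]
    return Design(
        "sim", "incidence",
        pd.DataFrame(X, columns=names),
        pd.Series(y),
        pd.Series(np.arange(n).astype(str)),
    )


class TestFitIndex:
    def test_huge_penalty_zeroes_coefficients(self):
        d = simulate_logistic(500, np.array([1.0, -1.0]), 0.0, seed=0)
        ix = fit_index(d, PenaltySpec(strength=1e6))
        assert all(abs(v) < 1e-6 for v in ix.coefficients.values())

    def test_parameter_recovery_with_zero_penalty(self):
        beta = np.array([0.5, -0.8, 0.3, 0.0, 0.6, -0.2])
        d = simulate_logistic(20000, beta, -1.0, seed=3)
        ix = fit_index(d, PenaltySpec(strength=1e-10, max_iter=2000))
        # 95% CI from an independent unpenalized ML fit's standard errors
        sm_fit = sm.Logit(d.y, sm.add_constant(d.X)).fit(disp=0)
        se = sm_fit.bse
        assert abs(ix.intercept - (-1.0)) < 1.96 * se["const"]
        for name, true in zip(d.X.columns, beta):
            assert abs(ix.coefficients[name] - true) < 1.96 * se[name]
        # calibration slope: logit of outcome on the fitted linear predictor
        eta = ix.intercept + d.X.to_numpy() @ ix.weights()
        slope = sm.Logit(d.y, sm.add_constant(eta)).fit(disp=0).params.iloc[1]
        assert 0.9 < slope < 1.1

    def test_duplicated_column_elastic_net_succeeds(self):
        d = simulate_logistic(500, np.array([1.0]), 0.0, seed=1)
        d.X["x0_copy"] = d.X["x0"]
        ix = fit_index(d, PenaltySpec(kind="elastic_net", l1_ratio=0.5, strength=0.01))
        assert np.isfinite(list(ix.coefficients.values())).all()

    def test_degenerate_outcome_error_names_outcome(self, registry):
        d = simulate_logistic(100, np.array([0.5]), 0.0, seed=2)
        d.y[:] = 1
        d.outcome_name = "stroke"
        with pytest.raises(ValueError, match="stroke"):
            fit_index(d, PenaltySpec(strength=0.01))

    def test_penalty_path_sparsity_monotone(self):
        d = simulate_logistic(2000, np.array([0.8, -0.5, 0.3, 0.1, 0.05]), -0.5, seed=4)
        counts = []
        for strength in (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0):
            ix = fit_index(d, PenaltySpec(kind="lasso", strength=strength))
            counts.append(sum(1 for v in ix.coefficients.values() if abs(v) > 1e-8))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cv_grid_selects_a_grid_value(self):
        d = simulate_logistic(1500, np.array([0.8, -0.5]), -0.5, seed=5)
        grid = (1e-3, 1e-1, 10.0)
        ix = fit_index(d, PenaltySpec(strength_grid=grid, cv_folds=3))
        assert ix.penalty["strength"] in grid


class TestPredictProbability:
    def test_all_zero_coefficients_gives_half(self):
        ix = fit_index(simulate_logistic(200, np.array([0.5]), 0.0, 0),
                       PenaltySpec(strength=1e6))
        ix.intercept = 0.0
        assert predict_probability(ix, {"x0": 3.0}) == pytest.approx(0.5)

    def test_intercept_closed_form(self):
        ix = fit_index(simulate_logistic(200, np.array([0.5]), 0.0, 0),
                       PenaltySpec(strength=1e6))
        ix.intercept = np.log(1 / 3)
        ix.coefficients = {"x0": 0.0}
        assert predict_probability(ix, {"x0": 1.0}) == pytest.approx(0.25)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        d = simulate_logistic(300, np.array([0.4, -0.7, 0.2]), 0.3, seed=6)
        ix = fit_index(d, PenaltySpec(strength=0.01))
        for _ in range(20):
            vec = {name: float(v) for name, v in
                   zip(d.X.columns, rng.standard_normal(3))}
            eta = ix.intercept + sum(
                ix.coefficients[k] * vec[k] for k in ix.coefficients
            )
            assert predict_probability(ix, vec) == pytest.approx(expit(eta))

    def test_missing_covariate_named(self):
        d = simulate_logistic(200, np.array([0.5, 0.2]), 0.0, seed=7)
        ix = fit_index(d, PenaltySpec(strength=0.01))
        with pytest.raises(KeyError, match="x1"):
            predict_probability(ix, {"x0": 1.0})


class TestBootstrap:
    def test_zero_replicates_empty(self):
        d = simulate_logistic(200, np.array([0.5]), 0.0, seed=9)
        b = bootstrap_uncertainty(d, PenaltySpec(strength=0.01), 0)
        assert b.n_replicates == 0

    def test_same_seed_identical(self):
        d = simulate_logistic(300, np.array([0.5]), 0.0, seed=10)
        b1 = bootstrap_uncertainty(d, PenaltySpec(strength=0.01), 5, seed=3)
        b2 = bootstrap_uncertainty(d, PenaltySpec(strength=0.01), 5, seed=3)
        np.testing.assert_array_equal(b1.coefficients, b2.coefficients)

    def test_replicate_mean_close_to_point_estimate(self):
        d = simulate_logistic(2000, np.array([0.6, -0.4]), -0.8, seed=11)
        spec = PenaltySpec(strength=1e-6, max_iter=1000)
        ix = fit_index(d, spec)
        b = bootstrap_uncertainty(d, spec, 30, seed=4)
        se = b.intercepts.std(ddof=1) / np.sqrt(b.n_replicates)
        # bootstrap-mean intercept consistent with the point estimate
        assert abs(b.intercepts.mean() - ix.intercept) < 3 * max(se, 1e-6) + 0.05
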