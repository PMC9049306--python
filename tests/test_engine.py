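"""Simulation engine: cycle mechanics, closed-form checks, invariants."""

import numpy as np
import pytest
from scipy.special import logit

from scdsim.engine import (
    EligibilityRule,
    IndividualState,
    MortalityModel,
    PopulationSpec,
    SimulationModels,
    Strategy,
    TreatmentEffect,
    advance_year,
    check_eligibility,
    common_care,
    run_cohort,
    sample_initial_state,
    simulate_lifetime,
)
from scdsim.features import feature_names
from scdsim.indices import PredictionIndex
from scdsim.rng import spawn_children


def intercept_models(registry, probs=None, mortality=None):
    """Models with intercept-only incidence indices at given annual probs."""
    probs = probs or {}
    schema = feature_names("incidence", registry)
    indices = {
        name: PredictionIndex(
            name, "incidence", "logit", float(logit(p)),
            {f: 0.0 for f in schema},
        )
        for name, p in probs.items()
    }
    return SimulationModels(registry, indices, mortality or MortalityModel(
        a_female=0.0, a_male=0.0
    ))


def fresh_state(models, age=20.0, sex_female=True, birth_year=1996):
    return IndividualState(models, age=age, sex_female=sex_female, birth_year=birth_year)


VOE = "vaso_occlusive_pain_episodes"


class TestEligibility:
    def test_enough_severe_events(self, registry):
        m = intercept_models(registry)
        s = fresh_state(m)
        s.hist[m.dis_names.index(VOE)] = 4
        assert check_eligibility(s, EligibilityRule(min_severe_events=3))

    def test_stroke_alone_qualifies(self, registry):
        m = intercept_models(registry)
        s = fresh_state(m)
        s.hist[m.dis_names.index("stroke")] = 1
        assert check_eligibility(s, EligibilityRule(min_severe_events=3))

    def test_no_severe_history_ineligible(self, registry):
        m = intercept_models(registry)
        s = fresh_state(m)
        s.hist[m.dis_names.index("fever")] = 10  # not severity-marked
        assert not check_eligibility(s, EligibilityRule(min_severe_events=3))


class TestAdvanceYear:
    def test_risk_ratio_halves_draw_probability(self, registry):
        m = intercept_models(registry, {VOE: 0.30})
        effect = TreatmentEffect(p_symptom_free=1.0, risk_ratios={VOE: 0.5})
        n, hits = 4000, 0
        rng = np.random.default_rng(0)
        for _ in range(n):
            s = fresh_state(m)
            s.cured = True
            s.strategy_received = "gene_therapy"
            rec = advance_year(s, rng, strategy_effect=effect)
            hits += VOE in rec.acute_events
        se = np.sqrt(0.15 * 0.85 / n)
        assert abs(hits / n - 0.15) < 3 * se

    def test_risk_ratio_above_one_with_high_probability_errors(self, registry):
        m = intercept_models(registry, {VOE: 0.8})
        effect = TreatmentEffect(p_symptom_free=1.0, risk_ratios={VOE: 1.5})
        s = fresh_state(m)
        s.cured = True
        s.strategy_received = "gene_therapy"
        with pytest.raises(ValueError, match=VOE):
            advance_year(s, np.random.default_rng(0), strategy_effect=effect)

    def test_full_suppression_leaves_only_aging_and_mortality(self, registry):
        probs = {a.name: 0.3 for a in registry.disease_attributes}
        m = intercept_models(registry, probs)
        effect = TreatmentEffect(
            p_symptom_free=1.0,
            risk_ratios={a.name: 0.0 for a in registry.disease_attributes},
        )
        s = fresh_state(m)
        s.cured = True
        s.strategy_received = "gene_therapy"
        rng = np.random.default_rng(1)
        for _ in range(30):
            if not s.alive:
                break
            advance_year(s, rng, strategy_effect=effect)
        assert s.dis_flags.sum() == 0
        assert s.hist.sum() == 0
        assert s.age > 20

    def test_same_seed_identical_record(self, registry):
        probs = {a.name: 0.2 for a in registry.disease_attributes}
        m = intercept_models(registry, probs)
        recs = []
        for _ in range(2):
            s = fresh_state(m)
            rng = np.random.default_rng(123)
            recs.append(advance_year(s, rng))
        np.testing.assert_array_equal(recs[0].dis_flags, recs[1].dis_flags)
        np.testing.assert_array_equal(recs[0].util, recs[1].util)
        assert recs[0].acute_events == recs[1].acute_events
        assert recs[0].died == recs[1].died

    def test_dead_individual_cannot_advance(self, registry):
        m = intercept_models(registry)
        s = fresh_state(m)
        s.alive = False
        with pytest.raises(ValueError):
            advance_year(s, np.random.default_rng(0))


class TestLifetimes:
    def test_certain_death_gives_one_year(self, registry):
        m = intercept_models(registry, mortality=MortalityModel(a_female=1.0, a_male=1.0, b=0.0))
        traj = simulate_lifetime(fresh_state(m), common_care(), np.random.default_rng(0))
        assert traj.years_lived == 1
        assert traj.died

    def test_constant_hazard_mean_survival_is_geometric(self, registry):
        # q = 0.05 every year: mean years lived = 1/q (death year counted)
        q = 0.05
        m = intercept_models(registry, mortality=MortalityModel(a_female=q, a_male=q, b=0.0))
        n = 10000
        children = spawn_children(np.random.SeedSequence([17]), n)
        lengths = []
        for i in range(n):
            rng = np.random.default_rng(children[i])
            traj = simulate_lifetime(
                fresh_state(m, age=0.0, birth_year=2016), common_care(),
                rng, horizon_age=10**6,
            )
            lengths.append(traj.years_lived)
        mean = np.mean(lengths)
        se = np.sqrt((1 - q) / q**2 / n)
        assert abs(mean - 1 / q) < 3 * se

    def test_cured_responder_with_zero_risk_never_onsets(self, registry):
        probs = {a.name: 0.4 for a in registry.disease_attributes}
        m = intercept_models(
            registry, probs, MortalityModel(a_female=0.02, a_male=0.02, b=0.0)
        )
        strategy = Strategy(
            name="gene_therapy",
            effect=TreatmentEffect(
                p_symptom_free=1.0,
                risk_ratios={a.name: 0.0 for a in registry.disease_attributes},
            ),
            eligibility=EligibilityRule(min_severe_events=1),
        )
        s = fresh_state(m)
        s.hist[m.dis_names.index(VOE)] = 3  # eligible
        traj = simulate_lifetime(s, strategy, np.random.default_rng(5), horizon_age=60)
        assert traj.cured
        for rec in traj.records:
            assert rec.dis_flags.sum() == 0

    def test_acute_events_do_not_persist(self, registry):
        m = intercept_models(registry, {VOE: 0.5},
                             MortalityModel(a_female=0.0, a_male=0.0))
        s = fresh_state(m)
        rng = np.random.default_rng(2)
        i = m.dis_names.index(VOE)
        after_true = []
        prev = False
        for _ in range(200):
            rec = advance_year(s, rng)
            cur = bool(rec.dis_flags[i])
            if prev:
                after_true.append(cur)
            prev = cur
        # an event year is followed by a non-event year about half the time
        frac = np.mean(after_true)
        assert 0.35 < frac < 0.65


class TestRunCohort:
    def test_n1_matches_simulate_lifetime_on_first_substream(self, registry):
        probs = {a.name: 0.1 for a in registry.disease_attributes}
        m = intercept_models(registry, probs,
                             MortalityModel(a_female=0.03, a_male=0.03, b=0.0))
        spec = PopulationSpec(age_mean=20, age_sd=5, prop_female=0.5, horizon_age=80)
        trajs, summary = run_cohort(1, spec, common_care(), m, seed=11, collect=True)
        ss_main, ss_util = spawn_children(np.random.SeedSequence([11]), 1)[0].spawn(2)
        rng = np.random.default_rng(ss_main)
        state = sample_initial_state(m, spec, rng)
        traj = simulate_lifetime(state, common_care(), rng, horizon_age=80,
                                 rng_util=np.random.default_rng(ss_util))
        assert traj.years_lived == trajs[0].years_lived
        for a, b in zip(traj.records, trajs[0].records):
            np.testing.assert_array_equal(a.dis_flags, b.dis_flags)

    def test_doubling_n_preserves_prefix(self, registry):
        probs = {a.name: 0.1 for a in registry.disease_attributes}
        m = intercept_models(registry, probs,
                             MortalityModel(a_female=0.05, a_male=0.05, b=0.0))
        spec = PopulationSpec(age_mean=20, age_sd=5, horizon_age=70)
        t50, _ = run_cohort(50, spec, common_care(), m, seed=3, collect=True)
        t100, _ = run_cohort(100, spec, common_care(), m, seed=3, collect=True)
        for a, b in zip(t50, t100[:50]):
            assert a.years_lived == b.years_lived
            assert a.sex_female == b.sex_female
            for ra, rb in zip(a.records, b.records):
                np.testing.assert_array_equal(ra.dis_flags, rb.dis_flags)

    def test_lifetime_prevalence_matches_closed_form(self, registry):
        # constant incidence p over L fixed years: P = 1 - (1-p)^L
        p, L, n = 0.05, 20, 3000
        m = intercept_models(registry, {"asthma": p})
        spec = PopulationSpec(age_mean=5, age_sd=0.5, prior_voe_rate=0.0,
                              horizon_age=0)  # horizon set per-run below
        children = spawn_children(np.random.SeedSequence([23]), n)
        ever = 0
        for i in range(n):
            rng = np.random.default_rng(children[i])
            s = fresh_state(m, age=0.0, birth_year=2016)
            for _ in range(L):
                advance_year(s, rng)
            ever += s.hist[m.dis_names.index("asthma")] > 0
        expected = 1 - (1 - p) ** L
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(ever / n - expected) < 3 * se

    def test_identity_strategy_machinery_is_inert(self, registry):
        probs = {a.name: 0.1 for a in registry.disease_attributes}
        m = intercept_models(registry, probs,
                             MortalityModel(a_female=0.04, a_male=0.04, b=0.0))
        spec = PopulationSpec(age_mean=25, age_sd=8, horizon_age=90)
        inert = Strategy(
            name="gene_therapy",
            effect=TreatmentEffect(p_symptom_free=1.0),
            eligibility=EligibilityRule(min_severe_events=10**9,
                                        stroke_qualifies=False),
        )
        _, s_cc = run_cohort(300, spec, common_care(), m, seed=9)
        _, s_in = run_cohort(300, spec, inert, m, seed=9)
        assert s_cc.mean_survival == s_in.mean_survival
        assert s_cc.lifetime_prevalence == s_in.lifetime_prevalence

    def test_chronic_monotone_and_no_post_death_activity(self, registry):
        probs = {a.name: 0.15 for a in registry.disease_attributes}
        m = intercept_models(registry, probs,
                             MortalityModel(a_female=0.05, a_male=0.05, b=0.0))
        spec = PopulationSpec(age_mean=20, age_sd=5, horizon_age=90)
        trajs, _ = run_cohort(200, spec, common_care(), m, seed=13, collect=True)
        chronic_ix = m.chronic_ix
        for t in trajs:
            for prev_rec, rec in zip(t.records, t.records[1:]):
                assert (rec.dis_flags[chronic_ix] >= prev_rec.dis_flags[chronic_ix]).all()
            if t.died:
                assert t.records[-1].died
                # death is the final record: nothing recorded afterwards
                assert all(not r.died for r in t.records[:-1])
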