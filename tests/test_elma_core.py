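"""Cox fits, product-integral probabilities, and expected durations."""

import numpy as np
import pandas as pd
import pytest

from elma import elma_core as ec
from elma import synthetic_registry as sr
from elma.states import N_STATES, PERMITTED_TRANSITIONS, STATE_INDEX, STATES, WORK

from conftest import prepare, start_vector


def records_df(rows, from_state="work", to_state="sickness_absence"):
    """rows: (entry, exit, event, level, weight)"""
    return pd.DataFrame(
        [dict(follow_up_id=i, from_state=from_state, to_state=to_state,
              entry_day=r[0], exit_day=r[1], event=r[2],
              exposure_level=r[3], weight=r[4]) for i, r in enumerate(rows)]
    )


def zero_model(h, j):
    e = np.zeros(0)
    return ec.TransitionModel(h, j, np.zeros(3), np.zeros((3, 3)),
                              e.astype(int), e, e)


def manual_models(overrides):
    """All-zero hazards except the (h, j) -> (days, increments) overrides."""
    models = {hj: zero_model(*hj) for hj in PERMITTED_TRANSITIONS}
    for (h, j), (days, inc) in overrides.items():
        m = models[(h, j)]
        m.event_days = np.asarray(days)
        m.base_increments = np.asarray(inc, float)
        m.increment_se = np.zeros(len(days))
        m.event_mass = np.asarray(inc, float)
        m.level_risk = np.zeros((len(days), 4))
    return models


def point_mass(state):
    pi = np.zeros(N_STATES)
    pi[STATE_INDEX[state]] = 1.0
    return pi


class TestFitTransitionHazard:
    def test_nelson_aalen_baseline_hand_computed(self):
        # risk sets 5, 4, 3 with one event at days 1, 2, 3:
        # A0(3) = 1/5 + 1/4 + 1/3 = 0.78333...
        rows = [
            (0, 1, 1, 0, 1.0), (0, 2, 1, 0, 1.0), (0, 3, 1, 0, 1.0),
            (0, 3, 0, 0, 1.0), (0, 4, 0, 0, 1.0),
        ]
        m = ec.fit_transition_hazard(records_df(rows))
        assert np.allclose(m.base_increments, [1 / 5, 1 / 4, 1 / 3])
        assert m.cumulative_baseline(3) == pytest.approx(1 / 5 + 1 / 4 + 1 / 3)
        assert np.allclose(m.beta, 0.0)

    def test_zero_events_degenerates_to_zero_hazard(self):
        m = ec.fit_transition_hazard(records_df([(0, 730, 0, 0, 1.0)] * 4))
        assert len(m.event_days) == 0
        assert "no_events" in m.flags

    def test_two_group_beta_matches_grid_search(self):
        # one event per exposure group, no ties: compare against a
        # brute-force maximizer of the Breslow partial likelihood
        rows = [
            (0, 3, 1, 1, 1.0), (0, 5, 1, 0, 1.0),
            (0, 7, 0, 0, 1.0), (0, 8, 0, 1, 1.0),
        ]
        entry = np.array([r[0] for r in rows], float)
        exit_ = np.array([r[1] for r in rows], float)
        event = np.array([r[2] for r in rows])
        lv1 = np.array([r[3] for r in rows])

        def loglik(b):
            ll = 0.0
            for t in exit_[event == 1]:
                at_risk = (entry < t) & (exit_ >= t)
                who = (exit_ == t) & (event == 1)
                ll += b * lv1[who].sum() - np.log(np.exp(b * lv1[at_risk]).sum())
            return ll

        grid = np.arange(-5, 5, 1e-4)
        best = grid[np.argmax([loglik(b) for b in grid])]
        m = ec.fit_transition_hazard(records_df(rows))
        assert m.beta[0] == pytest.approx(best, abs=1e-3)

    def test_monotone_level_capped_and_flagged(self):
        rows = [(0, 5, 1, 0, 1.0), (0, 9, 0, 0, 1.0), (0, 9, 0, 1, 1.0)]
        m = ec.fit_transition_hazard(records_df(rows))
        assert m.beta[0] == -ec.BETA_CAP
        assert any(f.startswith("monotone") for f in m.flags)

    def test_weighted_fit_matches_lifelines_on_tie_free_data(self):
        # continuous exit times (no ties): Efron == Breslow, so lifelines
        # is an independent oracle for the weighted coefficient
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 400
        lv = rng.integers(0, 2, n)  # levels 0 and 1
        rate = 0.02 * np.exp(0.6 * lv)
        t = rng.exponential(1.0 / rate)
        cens = rng.uniform(20, 80, n)
        exit_ = np.minimum(t, cens)
        event = (t <= cens).astype(int)
        w = rng.uniform(0.5, 2.0, n)
        rows = [(0.0, e, ev, l, wi) for e, ev, l, wi in zip(exit_, event, lv, w)]
        m = ec.fit_transition_hazard(records_df(rows))

        df = pd.DataFrame({"t": exit_, "e": event, "lv1": lv, "w": w})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e", weights_col="w", robust=False)
        assert m.beta[0] == pytest.approx(cph.params_["lv1"], abs=1e-4)


class TestTransitionProbability:
    def test_time_zero_is_identity(self):
        models = manual_models({})
        path = ec.transition_probability(models, 0, point_mass(WORK))
        assert np.allclose(path.P[0], np.eye(N_STATES))

    def test_zero_hazards_identity_forever(self):
        path = ec.transition_probability(manual_models({}), 0, point_mass(WORK))
        e = ec.expected_durations(path)
        assert e[STATE_INDEX[WORK]] == pytest.approx(730.0)

    def test_dense_jumps_recover_exponential_decay(self):
        lam, spacing = 0.002, 0.1
        days = np.arange(spacing, 730.0 + spacing / 2, spacing)
        models = manual_models({
            (WORK, "death"): (days, np.full(len(days), lam * spacing)),
        })
        path = ec.transition_probability(models, 0, point_mass(WORK))
        p_death = path.P[-1, STATE_INDEX[WORK], STATE_INDEX["death"]]
        expect = 1 - np.exp(-lam * 730)
        assert abs(p_death - expect) / expect < 0.01

    def test_occupation_rows_stay_stochastic(self, single_stratum_cohort):
        _, base, rec = prepare(single_stratum_cohort)
        models = ec.fit_all_transitions(rec)
        pi = start_vector(single_stratum_cohort.config)
        for lv in (0, 2):
            path = ec.transition_probability(models, lv, pi)
            assert np.abs(path.P.sum(axis=2) - 1.0).max() < 1e-8
            occ = pi @ path.P
            assert np.abs(occ.sum(axis=1) - 1.0).max() < 1e-8


class TestExpectedDurations:
    def test_conservation_for_fitted_paths(self, single_stratum_cohort):
        _, base, rec = prepare(single_stratum_cohort)
        models = ec.fit_all_transitions(rec)
        pi = start_vector(single_stratum_cohort.config)
        e = ec.expected_durations(ec.transition_probability(models, 1, pi))
        assert e.sum() == pytest.approx(730.0, abs=1e-6)

    def test_monotonicity_in_single_hazard(self):
        # doubling work->sickness weakly decreases E_work, increases E_sick
        days = np.arange(10, 730, 10)
        base_inc = np.full(len(days), 0.0005 * 10)
        low = manual_models({(WORK, "sickness_absence"): (days, base_inc)})
        high = manual_models({(WORK, "sickness_absence"): (days, 2 * base_inc)})
        e_low = ec.expected_durations(ec.transition_probability(low, 0, point_mass(WORK)))
        e_high = ec.expected_durations(ec.transition_probability(high, 0, point_mass(WORK)))
        assert e_high[STATE_INDEX[WORK]] < e_low[STATE_INDEX[WORK]]
        assert e_high[STATE_INDEX["sickness_absence"]] > e_low[STATE_INDEX["sickness_absence"]]

    def test_duration_differences_reference_and_conservation(self):
        e = {0: np.array([700.0, 20, 5, 5, 0, 0, 0]),
             2: np.array([680.0, 35, 7, 8, 0, 0, 0])}
        d = ec.duration_differences(e)
        assert np.allclose(d[0], 0.0)
        assert d[2].sum() == pytest.approx(0.0)
        assert d[2][0] == pytest.approx(-20.0)


class TestConfidenceIntervals:
    def test_zero_variance_limit_gives_degenerate_ci(self):
        days = np.arange(10, 730, 10)
        models = manual_models({
            (WORK, "sickness_absence"): (days, np.full(len(days), 0.001)),
        })
        # level_risk zero and increment_se zero -> draws equal the point path
        draws = ec.sample_duration_draws(models, {0: point_mass(WORK)}, 50, seed=1)
        assert np.allclose(draws[0].std(axis=0), 0.0, atol=1e-12)

    def test_ci_contains_point_estimate(self, single_stratum_cohort):
        _, base, rec = prepare(single_stratum_cohort)
        tab, _, _ = ec.estimate_state_durations(
            rec, base, stratum="M:35-49", n_resamples=200, seed=9
        )
        assert (tab["ci_low"] <= tab["expected_days"] + 1e-9).all()
        assert (tab["ci_high"] >= tab["expected_days"] - 1e-9).all()
        assert (tab["delta_low"] <= tab["delta_days"] + 1e-9).all()
        assert (tab["delta_high"] >= tab["delta_days"] - 1e-9).all()


class TestCrudeDurations:
    def base2(self):
        return pd.DataFrame([
            dict(follow_up_id=1, stratum="M:35-49", exposure_level=0),
            dict(follow_up_id=2, stratum="M:35-49", exposure_level=0),
        ])

    def test_two_person_mean(self):
        epi = pd.DataFrame([
            dict(person_id=1, follow_up_id=1, start_day=0, end_day=730, state="work"),
            dict(person_id=2, follow_up_id=2, start_day=0, end_day=730, state="unemployment"),
        ])
        out = ec.crude_durations(epi, self.base2())
        work = out[(out.state == "work")]["crude_days"].iloc[0]
        assert work == pytest.approx(365.0)

    def test_degenerate_cohort_matches_elma(self):
        # every person shares one trajectory: crude == ELMA == observed days
        epi = pd.DataFrame([
            dict(person_id=i, follow_up_id=i, start_day=0, end_day=200, state="work")
            for i in range(1, 4)
        ] + [
            dict(person_id=i, follow_up_id=i, start_day=200, end_day=730,
                 state="sickness_absence") for i in range(1, 4)
        ])
        base = pd.DataFrame([
            dict(follow_up_id=i, stratum="M:35-49", exposure_level=0,
                 start_state="work") for i in range(1, 4)
        ])
        crude = ec.crude_durations(epi, base).set_index("state")["crude_days"]
        rec = pd.concat([
            pd.DataFrame([dict(follow_up_id=i, from_state="work",
                               to_state=j, entry_day=0, exit_day=200,
                               event=int(j == "sickness_absence"),
                               exposure_level=0, weight=1.0)
                          for i in range(1, 4)
                          for j in STATES if j != "work"]),
            pd.DataFrame([dict(follow_up_id=i, from_state="sickness_absence",
                               to_state=j, entry_day=200, exit_day=730, event=0,
                               exposure_level=0, weight=1.0)
                          for i in range(1, 4)
                          for j in STATES if j != "sickness_absence"]),
        ])
        models = ec.fit_all_transitions(rec)
        e = ec.expected_durations(ec.transition_probability(models, 0, point_mass(WORK)))
        assert e[STATE_INDEX[WORK]] == pytest.approx(crude["work"]) == pytest.approx(200.0)
        assert e[STATE_INDEX["sickness_absence"]] == pytest.approx(530.0)
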