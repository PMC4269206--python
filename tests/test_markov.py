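"""Decision tree and Markov cohort mechanics."""

import numpy as np
import pytest

from acs_cea.markov import (
    StateDistribution,
    StateId,
    annual_death_prob,
    apply_hazard_ratio,
    run_markov,
    run_year_one,
)
from acs_cea.parameters import LifeTable
from acs_cea.synthetic import GompertzMakehamParams, generate_life_table
from acs_cea.uncertainty import apply_overrides

import pandas as pd


def _constant_life_table(q, max_age=110):
    rows = [
        (a, sex, q if a < max_age else 1.0)
        for sex in ("male", "female")
        for a in range(0, max_age + 1)
    ]
    return LifeTable(pd.DataFrame(rows, columns=["age", "sex", "qx"]))


class TestApplyHazardRatio:
    def test_identity_and_closed_form(self):
        assert apply_hazard_ratio(0.02, 1.0) == pytest.approx(0.02)
        assert apply_hazard_ratio(0.02, 1.6) == pytest.approx(1 - 0.98**1.6)

    def test_absorbing(self):
        assert apply_hazard_ratio(1.0, 0.3) == 1.0

    def test_out_of_range_probability(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(1.2, 1.0)


class TestAnnualDeathProb:
    def test_reduces_to_life_table_when_unity(self, overall_config, german_lt):
        cfg = apply_overrides(
            overall_config,
            {
                "longterm.q_cv_fatal": 0.0,
                "hazard_ratios": {
                    "hr_no_event": 1.0,
                    "hr_mi_y1": 1.0,
                    "hr_mi_y2plus": 1.0,
                    "hr_stroke_y1": 1.0,
                    "hr_stroke_y2plus": 1.0,
                },
            },
        )
        for age in (62, 75, 90):
            q = annual_death_prob(
                age, cfg.cohort, german_lt, cfg.longterm, cfg.hazard_ratios,
                StateId.NO_EVENT,
            )
            assert q == pytest.approx(
                german_lt.sex_weighted_qx(age, cfg.cohort.male_fraction), abs=1e-15
            )

    def test_hazard_additivity_closed_form(self, overall_config):
        # qx = 0.010 combined with fatal-CV 0.019 on the hazard scale
        lt = _constant_life_table(0.010)
        q = annual_death_prob(
            70, overall_config.cohort, lt, overall_config.longterm,
            overall_config.hazard_ratios, StateId.NO_EVENT,
        )
        assert q == pytest.approx(1 - 0.990 * 0.981, abs=1e-12)

    def test_stroke_tunnel_uses_first_year_hazard_ratio(self, overall_config, german_lt):
        args = (
            70, overall_config.cohort, german_lt, overall_config.longterm,
            overall_config.hazard_ratios,
        )
        q_y1 = annual_death_prob(*args, StateId.STROKE_Y1)
        q_post = annual_death_prob(*args, StateId.STROKE_POST)
        q_ne = annual_death_prob(*args, StateId.NO_EVENT)
        # HR 3.23 in the first post-stroke year, 1.5 afterwards, 1 without event
        h_ne = -np.log1p(-q_ne)
        assert -np.log1p(-q_y1) == pytest.approx(3.23 * h_ne, rel=1e-12)
        assert -np.log1p(-q_post) == pytest.approx(1.5 * h_ne, rel=1e-12)

    def test_age_beyond_table_raises(self, overall_config, german_lt):
        with pytest.raises(ValueError, match="span"):
            annual_death_prob(
                150, overall_config.cohort, german_lt, overall_config.longterm,
                overall_config.hazard_ratios, StateId.NO_EVENT,
            )


class TestRunYearOne:
    def test_end_distribution_and_qalys(self, overall_config):
        res = run_year_one(
            overall_config.arm_ticagrelor,
            overall_config.costs,
            overall_config.costs.dtc_ticagrelor,
        )
        dist = res.end_distribution
        assert dist[StateId.NO_EVENT] == pytest.approx(0.915)
        assert dist[StateId.MI_Y1] == pytest.approx(0.041)
        expected_qaly = 0.041 * 0.817 + 0.008 * 0.748 + 0.036 * 0.259 + 0.915 * 0.875
        assert res.qalys == pytest.approx(expected_qaly, abs=1e-12)
        assert res.life_years == pytest.approx(1 - 0.5 * 0.036)

    def test_event_and_death_cost_weighted_sum(self, overall_config):
        res = run_year_one(
            overall_config.arm_clopidogrel, overall_config.costs, 0.0
        )
        expected = 0.049 * 9558 + 0.008 * 14925 + 0.050 * 8650
        assert res.cost == pytest.approx(expected)
        assert expected == pytest.approx(1020.2, abs=0.5)

    def test_drug_cost_exposure_of_decedents(self, overall_config):
        arm = overall_config.arm_ticagrelor
        res = run_year_one(arm, overall_config.costs, 2.90)
        drug = res.cost - (0.041 * 9558 + 0.008 * 14925 + 0.036 * 8650)
        assert drug == pytest.approx(365 * 2.90 * (1 - 0.036 * 0.5))


class TestRunMarkov:
    def test_no_transitions_stay_in_no_event(self, overall_config):
        cfg = apply_overrides(
            overall_config,
            {
                "longterm.q_mi": 0.0,
                "longterm.q_stroke": 0.0,
                "longterm.q_cv_fatal": 0.0,
                "cohort.max_age": 72,
            },
        )
        lt = _constant_life_table(0.0)
        start = StateDistribution({StateId.NO_EVENT: 1.0})
        trace = run_markov(start, cfg, lt)
        assert len(trace.cycles) == 10
        for _, _, dist in trace.cycles:
            assert dist[StateId.NO_EVENT] == pytest.approx(1.0, abs=1e-15)

    def test_constant_mortality_matches_geometric_sum(self, overall_config):
        """Undiscounted life-years over 40 cycles with q = 0.05 equal the
        geometric series sum_{t=0}^{39} 0.95^t (start-of-cycle accrual)."""
        cfg = apply_overrides(
            overall_config,
            {
                "longterm.q_mi": 0.0,
                "longterm.q_stroke": 0.0,
                "longterm.q_cv_fatal": 0.0,
                "cohort.start_age": 60,
                "cohort.max_age": 100,
            },
        )
        lt = _constant_life_table(0.05)
        start = StateDistribution({StateId.NO_EVENT: 1.0})
        trace = run_markov(start, cfg, lt)
        assert len(trace.cycles) == 40
        ly = sum(dist.living for _, _, dist in trace.cycles)
        oracle = (1 - 0.95**40) / 0.05  # closed-form geometric sum
        assert ly == pytest.approx(oracle, abs=1e-9)

    def test_rows_sum_to_one_and_death_monotone(self, overall_config, german_lt):
        res = run_year_one(
            overall_config.arm_clopidogrel,
            overall_config.costs,
            overall_config.costs.dtc_clopidogrel,
        )
        trace = run_markov(res.end_distribution, overall_config, german_lt)
        dead = [dist[StateId.DEAD] for _, _, dist in trace.cycles]
        for _, _, dist in trace.cycles:
            assert sum(dist.occupancy.values()) == pytest.approx(1.0, abs=1e-12)
            assert min(dist.occupancy.values()) >= 0.0
        assert np.all(np.diff(dead) >= 0)

    def test_life_table_survival_reproduced_without_events(self, overall_config, german_lt):
        cfg = apply_overrides(
            overall_config,
            {
                "longterm.q_mi": 0.0,
                "longterm.q_stroke": 0.0,
                "longterm.q_cv_fatal": 0.0,
                "hazard_ratios.hr_no_event": 1.0,
            },
        )
        start = StateDistribution({StateId.NO_EVENT: 1.0})
        trace = run_markov(start, cfg, german_lt)
        surv = 1.0
        for t, age, dist in trace.cycles:
            assert dist[StateId.NO_EVENT] == pytest.approx(surv, abs=1e-12)
            surv *= 1 - german_lt.sex_weighted_qx(age, cfg.cohort.male_fraction)

    def test_tunnel_lasts_exactly_one_cycle(self, overall_config, german_lt):
        res = run_year_one(
            overall_config.arm_ticagrelor,
            overall_config.costs,
            overall_config.costs.dtc_ticagrelor,
        )
        trace = run_markov(res.end_distribution, overall_config, german_lt)
        cfg = overall_config
        rows = list(trace.cycles) + [(None, None, trace.final)]
        for (t, age, dist), (_, _, nxt) in zip(rows[:-1], rows[1:]):
            q_death = annual_death_prob(
                age, cfg.cohort, german_lt, cfg.longterm, cfg.hazard_ratios,
                StateId.MI_Y1,
            )
            survivors = dist[StateId.MI_Y1] * (1 - q_death)
            q_post = annual_death_prob(
                age, cfg.cohort, german_lt, cfg.longterm, cfg.hazard_ratios,
                StateId.MI_POST,
            )
            expected_post = survivors + dist[StateId.MI_POST] * (1 - q_post)
            assert nxt[StateId.MI_POST] == pytest.approx(expected_post, abs=1e-12)

    def test_bad_start_distribution_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            StateDistribution({StateId.NO_EVENT: 0.7})


class TestMicroSimulationOracle:
    def test_cohort_trace_matches_individual_simulation(self, overall_config):
        """Five-cycle toy model: the deterministic cohort trace agrees with a
        vectorised micro-simulation of 10^6 independent patients."""
        cfg = apply_overrides(
            overall_config,
            {"cohort.start_age": 62, "cohort.max_age": 67},
        )
        lt = generate_life_table(GompertzMakehamParams(a=0.01, b=1e-4, c=0.09))
        res = run_year_one(cfg.arm_ticagrelor, cfg.costs, cfg.costs.dtc_ticagrelor)
        trace = run_markov(res.end_distribution, cfg, lt)
        assert len(trace.cycles) == 5

        n = 1_000_000
        rng = np.random.default_rng(2013)
        states = list(StateId)
        code = {s: i for i, s in enumerate(states)}
        start = res.end_distribution
        pop = rng.choice(
            len(states), size=n, p=[start[s] for s in states]
        )
        lt_q = cfg.longterm
        for t, age, dist in trace.cycles:
            # compare occupancy at the start of each cycle
            for s in states:
                sim = np.mean(pop == code[s])
                assert abs(sim - dist[s]) < 1e-3, (t, s)
            death_p = np.zeros(len(states))
            for s in states:
                if s is not StateId.DEAD:
                    death_p[code[s]] = annual_death_prob(
                        age, cfg.cohort, lt, lt_q, cfg.hazard_ratios, s
                    )
            u = rng.random(n)
            dies = u < death_p[pop]
            new_pop = pop.copy()
            new_pop[dies] = code[StateId.DEAD]
            alive_ne = (~dies) & (pop == code[StateId.NO_EVENT])
            v = rng.random(n)
            new_pop[alive_ne & (v < lt_q.q_mi)] = code[StateId.MI_Y1]
            new_pop[
                alive_ne & (v >= lt_q.q_mi) & (v < lt_q.q_mi + lt_q.q_stroke)
            ] = code[StateId.STROKE_Y1]
            for src, dst in (
                (StateId.MI_Y1, StateId.MI_POST),
                (StateId.STROKE_Y1, StateId.STROKE_POST),
            ):
                new_pop[(~dies) & (pop == code[src])] = code[dst]
            pop = new_pop
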