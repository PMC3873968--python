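import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gccea.epidemiology import RateTable
from gccea.markov import (
    CohortTrace,
    SubgroupResult,
    aggregate,
    annual_stage_death_prob,
    combine_competing_risks,
    detection_weight,
    evaluate_strategies,
    lifetime_outcomes,
    ogd_delivered,
    run_cohort,
    split_incidence,
    stage_cohort_survival,
    stage_mix_at_diagnosis,
)
from gccea.parameters import set_param


def bisection_split_oracle(q_pop, p, odds_ratio, tol=1e-14):
    """Independent bisection on the mixture/odds-ratio constraints."""

    def q_high_of(q_low):
        o = odds_ratio * q_low / (1 - q_low)
        return o / (1 + o)

    lo, hi = 0.0, q_pop
    for _ in range(200):
        mid = (lo + hi) / 2
        if p * q_high_of(mid) + (1 - p) * mid - q_pop > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    q_low = (lo + hi) / 2
    return q_low, q_high_of(q_low)


def zero_incidence(params):
    params.incidence = RateTable(
        "incidence", {k: 0.0 for k in params.incidence.entries}
    )
    return params


def zero_costs(params):
    c = params.costs
    c.baseline_ogd = c.followup_ogd = 0.0
    c.dx_staging_program = c.dx_staging_usual = 0.0
    c.treatment_by_stage = (0.0, 0.0, 0.0, 0.0)
    c.post_treatment_followup_annual = 0.0
    return params


def discounted_life_expectancy(params, sex, start_age):
    """Life-table recursion with the engine's termination semantics."""
    mort = params.mortality
    r = params.econ.discount_rate
    last_age = min(params.econ.max_age, mort.max_age(sex))
    alive, dead, t, total = 1.0, 0.0, 0, 0.0
    while True:
        total += alive * (1.0 + r) ** (-t)
        d = alive * mort.value(start_age + t, sex)
        alive -= d
        dead += d
        t += 1
        if dead >= params.econ.termination_fraction or start_age + t > last_age:
            return total


class TestSplitIncidence:
    def test_no_stratification_at_or_one(self):
        assert split_incidence(0.001, 0.135, 1.0) == (0.001, 0.001)

    def test_against_bisection_oracle(self):
        q_low, q_high = split_incidence(0.001, 0.135, 6.0)
        o_low, o_high = bisection_split_oracle(0.001, 0.135, 6.0)
        assert q_low == pytest.approx(o_low, abs=1e-12)
        assert q_high == pytest.approx(o_high, abs=1e-12)
        assert q_low == pytest.approx(5.97e-4, rel=5e-3)
        assert q_high == pytest.approx(3.58e-3, rel=5e-3)

    def test_rare_disease_approximation(self):
        # the first-order approximation q_pop / (1 - p + p*OR) ignores the
        # odds->probability curvature, whose relative error scales with
        # q_high * OR; at OR=21.5 it only stays below 1% for q_pop <~ 2e-3
        for q_pop in (1e-5, 1e-4, 1e-3, 5e-3):
            for p in (0.065, 0.135, 0.27):
                for odds_ratio in (2.4, 6.0, 21.5):
                    if odds_ratio > 6.0 and q_pop > 1e-3:
                        continue
                    q_low, _ = split_incidence(q_pop, p, odds_ratio)
                    approx = q_pop / (1 - p + p * odds_ratio)
                    assert q_low == pytest.approx(approx, rel=0.01)

    def test_constraints_on_grid(self):
        for q_pop in (1e-4, 1e-3, 0.01, 0.1, 0.3):
            for p in (0.01, 0.135, 0.5, 0.9):
                for odds_ratio in (1.5, 6.0, 21.5, 100.0):
                    q_low, q_high = split_incidence(q_pop, p, odds_ratio)
                    mixture = p * q_high + (1 - p) * q_low
                    assert mixture == pytest.approx(q_pop, abs=1e-10)
                    odds_ratio_got = (q_high / (1 - q_high)) / (q_low / (1 - q_low))
                    assert odds_ratio_got == pytest.approx(odds_ratio, rel=1e-8)
                    assert q_low <= q_pop <= q_high

    def test_whole_population_high_risk_limit(self):
        q_low, q_high = split_incidence(0.002, 0.999999, 6.0)
        assert q_high == pytest.approx(0.002, rel=1e-4)

    def test_zero_incidence(self):
        assert split_incidence(0.0, 0.135, 6.0) == (0.0, 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            split_incidence(1.0, 0.135, 6.0)
        with pytest.raises(ValueError):
            split_incidence(0.001, 0.0, 6.0)
        with pytest.raises(ValueError):
            split_incidence(0.001, 0.135, 0.5)

    @given(
        q_pop=st.floats(1e-6, 0.5),
        p=st.floats(0.01, 0.99),
        odds_ratio=st.floats(1.0, 50.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_constraints_property(self, q_pop, p, odds_ratio):
        q_low, q_high = split_incidence(q_pop, p, odds_ratio)
        assert p * q_high + (1 - p) * q_low == pytest.approx(q_pop, abs=1e-10)
        assert q_low <= q_pop <= q_high


class TestStageDeathProb:
    def test_stage1(self, base_params):
        expected = 1.0 - 0.9**0.2
        assert annual_stage_death_prob(1, base_params.survival) == pytest.approx(
            expected, abs=1e-15
        )
        assert expected == pytest.approx(0.02085, abs=1e-5)

    def test_certain_survival(self, params):
        params.survival.five_year_survival = (1.0, 0.7, 0.4, 0.0)
        assert annual_stage_death_prob(1, params.survival) == 0.0

    def test_stage4_epsilon(self, base_params):
        expected = 1.0 - 0.001**0.2
        assert annual_stage_death_prob(4, base_params.survival) == pytest.approx(
            expected, abs=1e-15
        )
        assert expected == pytest.approx(0.749, abs=1e-3)

    def test_invalid_stage(self, base_params):
        with pytest.raises(ValueError):
            annual_stage_death_prob(0, base_params.survival)
        with pytest.raises(ValueError):
            annual_stage_death_prob(5, base_params.survival)

    def test_invalid_survival(self, params):
        params.survival.five_year_survival = (1.2, 0.7, 0.4, 0.0)
        with pytest.raises(ValueError):
            annual_stage_death_prob(1, params.survival)


class TestCompetingRisks:
    def test_zero_gc(self):
        assert combine_competing_risks(0.0, 0.02) == pytest.approx(0.02)

    def test_direct_arithmetic(self):
        assert combine_competing_risks(0.1, 0.02) == pytest.approx(0.118)

    def test_both_certain(self):
        assert combine_competing_risks(1.0, 1.0) == 1.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            combine_competing_risks(-0.1, 0.5)


class TestDetectionWeight:
    def test_none_strategy_zero(self, base_params):
        spec = base_params.strategies["none"]
        for cycle in range(5):
            for group in ("low", "high"):
                assert detection_weight(spec, group, cycle, 0.93) == 0.0

    def test_annual_surveillance_high_risk(self, base_params):
        spec = base_params.strategies["surveil1y"]
        for cycle in range(6):
            assert detection_weight(spec, "high", cycle, 0.93) == 0.93

    def test_two_yearly_interval_year(self, base_params):
        spec = base_params.strategies["surveil2y"]
        assert detection_weight(spec, "high", 1, 0.93) == pytest.approx(0.558)
        assert detection_weight(spec, "high", 2, 0.93) == 0.93
        assert detection_weight(spec, "high", 0, 0.93) == 0.93  # baseline year

    def test_screening_interval_fraction(self, base_params):
        spec = base_params.strategies["screen2y"]
        assert detection_weight(spec, "low", 3, 0.93) == pytest.approx(0.93 * 0.40)

    def test_combined_arm_groups(self, base_params):
        spec = base_params.strategies["screen2y_plus_surveil1y"]
        assert detection_weight(spec, "high", 3, 0.93) == 0.93
        assert detection_weight(spec, "low", 3, 0.93) == pytest.approx(0.93 * 0.40)
        assert detection_weight(spec, "low", 4, 0.93) == 0.93

    def test_low_risk_no_followup_after_baseline(self, base_params):
        spec = base_params.strategies["surveil1y"]
        assert detection_weight(spec, "low", 0, 0.93) == 0.93  # baseline OGD
        assert detection_weight(spec, "low", 1, 0.93) == 0.0

    def test_ogd_delivery_schedule(self, base_params):
        spec = base_params.strategies["surveil2y"]
        delivered = [ogd_delivered(spec, "high", t) for t in range(6)]
        assert delivered == [True, False, True, False, True, False]
        assert not any(
            ogd_delivered(base_params.strategies["none"], g, t)
            for g in ("low", "high")
            for t in range(6)
        )


class TestStageMix:
    def test_usual_at_zero(self, base_params):
        mix = stage_mix_at_diagnosis(
            0.0,
            base_params.stage_program.as_tuple(),
            base_params.stage_usual.as_tuple(),
        )
        assert mix == (0.07, 0.17, 0.33, 0.43)

    def test_program_at_one(self, base_params):
        mix = stage_mix_at_diagnosis(
            1.0,
            base_params.stage_program.as_tuple(),
            base_params.stage_usual.as_tuple(),
        )
        assert mix == (0.85, 0.04, 0.08, 0.03)

    def test_elementwise_average(self, base_params):
        mix = stage_mix_at_diagnosis(
            0.5,
            base_params.stage_program.as_tuple(),
            base_params.stage_usual.as_tuple(),
        )
        assert mix == pytest.approx((0.46, 0.105, 0.205, 0.23))
        assert sum(mix) == pytest.approx(1.0, abs=1e-12)


class TestRunCohort:
    def test_conservation(self, base_params):
        for name in base_params.strategies:
            trace = run_cohort(name, "male", 55, base_params)
            assert np.abs(trace.occupancy_totals() - 1.0).max() < 1e-12

    def test_matrix_product_oracle_three_cycles(self, params):
        # with zero incidence the model reduces to alive/dead; the first
        # three cycles must match an explicit transition-matrix product
        zero_incidence(params)
        trace = run_cohort("none", "female", 60, params)
        state = np.array([1.0, 0.0])  # (alive, dead)
        for t in range(3):
            q = params.mortality.value(60 + t, "female")
            matrix = np.array([[1.0 - q, 0.0], [q, 1.0]])
            state = matrix @ state
            assert trace.alive_fraction()[t] == pytest.approx(state[0], abs=1e-12)

    def test_zero_incidence_qaly_is_life_expectancy(self, params):
        zero_incidence(params)
        zero_costs(params)
        for sex, age in [("male", 50), ("female", 65)]:
            result = lifetime_outcomes(run_cohort("none", sex, age, params))
            assert result.cost == 0.0
            expected = discounted_life_expectancy(params, sex, age)
            assert result.qaly == pytest.approx(expected, abs=1e-9)

    def test_undiscounted_life_expectancy(self, params):
        zero_incidence(params)
        zero_costs(params)
        params.econ.discount_rate = 0.0
        result = lifetime_outcomes(run_cohort("surveil1y", "male", 60, params))
        expected = discounted_life_expectancy(params, "male", 60)
        assert result.qaly == pytest.approx(expected, abs=1e-9)

    def test_incident_mass_identical_across_arms(self, base_params):
        traces = {
            name: run_cohort(name, "male", 58, base_params)
            for name in base_params.strategies
        }
        reference = traces["none"].gc_incidence
        for name, trace in traces.items():
            n = min(len(reference), len(trace.gc_incidence))
            assert np.abs(trace.gc_incidence[:n] - reference[:n]).max() < 1e-10

    def test_detection_off_nests_reference(self, params):
        params.test.sensitivity = 0.0
        qalys = {}
        costs = {}
        for name in params.strategies:
            r = lifetime_outcomes(run_cohort(name, "female", 55, params))
            qalys[name] = r.qaly
            costs[name] = r.cost
        for name in params.strategies:
            assert qalys[name] == pytest.approx(qalys["none"], abs=1e-10)
            assert costs[name] >= costs["none"] - 1e-12  # program costs only

    def test_detection_off_and_free_ogd_costs_equal(self, params):
        params.test.sensitivity = 0.0
        params.costs.baseline_ogd = 0.0
        params.costs.followup_ogd = 0.0
        reference = lifetime_outcomes(run_cohort("none", "female", 55, params))
        for name in params.strategies:
            r = lifetime_outcomes(run_cohort(name, "female", 55, params))
            assert r.cost == pytest.approx(reference.cost, abs=1e-10)

    def test_downstaging_is_ordinal_not_incidence(self, base_params):
        none = run_cohort("none", "male", 55, base_params)
        s1y = run_cohort("surveil1y", "male", 55, base_params)
        # same incident mass, but more stage-1 diagnoses under surveillance
        stage1_cols = slice(2, 8)  # stage-1 occupancy columns
        assert s1y.states[5, stage1_cols].sum() > none.states[5, stage1_cols].sum()
        assert lifetime_outcomes(s1y).gc_deaths < lifetime_outcomes(none).gc_deaths

    def test_followup_ogd_cost_per_delivery(self, params):
        # isolate the per-OGD delivered cost: zero incidence, only the
        # follow-up OGD price is non-zero, annual surveillance
        zero_incidence(params)
        zero_costs(params)
        params.costs.followup_ogd = 340.0
        trace = run_cohort("surveil1y", "male", 60, params)
        # cycle 1: high-risk mass gets one OGD at 340 / (1 - 0.40) each
        high_mass = trace.states[0, 1]
        expected = high_mass * 340.0 / 0.60 / 1.03
        assert trace.cost[1] == pytest.approx(expected, rel=1e-12)

    def test_stage_survival_recovery(self, base_params):
        for stage in (1, 2, 3):
            s5 = base_params.survival.five_year_survival[stage - 1]
            survival = stage_cohort_survival(stage, 5, base_params)
            assert survival == pytest.approx(s5, abs=1e-9)

    def test_missing_table_cell_raises(self, params):
        params.incidence = RateTable(
            "incidence",
            {k: v for k, v in params.incidence.entries.items() if k[0] <= 70},
        )
        with pytest.raises(KeyError, match="no entry"):
            run_cohort("none", "male", 50, params)

    def test_termination(self, base_params):
        trace = run_cohort("none", "male", 50, base_params)
        assert trace.dead_fraction()[-1] >= base_params.econ.termination_fraction
        assert trace.dead_fraction()[-2] < base_params.econ.termination_fraction

    def test_half_cycle_correction_halves_first_cycle(self, params):
        zero_incidence(params)
        zero_costs(params)
        baseline = run_cohort("none", "male", 60, params)
        params.econ.half_cycle_correction = True
        corrected = run_cohort("none", "male", 60, params)
        assert corrected.qaly[0] == pytest.approx(0.5 * baseline.qaly[0])
        assert corrected.qaly[1] == pytest.approx(baseline.qaly[1])

    def test_trace_export_shape(self, base_params):
        trace = run_cohort("surveil2y", "female", 60, base_params)
        df = trace.to_frame()
        assert list(df.columns[:2]) == ["cycle", "age"]
        assert {"cost", "qaly", "ogd"} <= set(df.columns)
        assert len(df) == trace.n_cycles()


class TestStage4EpsilonInsensitivity:
    def test_results_stable_for_small_epsilon(self, params):
        results = {}
        for eps in (0.01, 0.001, 1e-4):
            params.survival.stage4_epsilon = eps
            r = lifetime_outcomes(run_cohort("surveil1y", "male", 60, params))
            results[eps] = r.qaly
        spread = max(results.values()) - min(results.values())
        assert spread < 5e-3


class TestLifetimeOutcomes:
    @staticmethod
    def _trace(cost, qaly, r=0.03):
        n = len(cost)
        return CohortTrace(
            strategy="none",
            sex="male",
            start_age=60,
            discount_rate=r,
            cycles=np.arange(n),
            ages=60 + np.arange(n),
            states=np.zeros((n, 28)),
            cost=np.asarray(cost, dtype=float),
            qaly=np.asarray(qaly, dtype=float),
            ogd=np.zeros(n),
            gc_incidence=np.zeros(n),
            gc_deaths=np.zeros(n),
        )

    def test_zero_cost_trace(self):
        assert lifetime_outcomes(self._trace([0.0], [0.5])).cost == 0.0

    def test_single_cycle_no_discounting(self):
        assert lifetime_outcomes(self._trace([0.0], [0.88])).qaly == 0.88

    def test_two_cycle_discounting(self, params):
        # engine stores already-discounted increments; build them explicitly
        trace = self._trace([0.0, 0.0], [1.0, 1.0 / 1.03])
        assert lifetime_outcomes(trace).qaly == pytest.approx(1.9709, abs=1e-4)


class TestAggregate:
    @staticmethod
    def _result(cost, age=50, sex="male"):
        return SubgroupResult("none", sex, age, cost, 10.0, 1.0, 0.01)

    def test_single_subgroup_unchanged(self):
        from gccea.epidemiology import PopulationWeights

        weights = PopulationWeights({(50, "male"): 1.0})
        pooled = aggregate({(50, "male"): self._result(100.0)}, weights)
        assert pooled.cost == pytest.approx(100.0)

    def test_equal_weights_mean(self):
        from gccea.epidemiology import PopulationWeights

        weights = PopulationWeights({(50, "male"): 0.5, (51, "male"): 0.5})
        pooled = aggregate(
            {
                (50, "male"): self._result(100.0),
                (51, "male"): self._result(300.0, age=51),
            },
            weights,
        )
        assert pooled.cost == pytest.approx(200.0)

    def test_weighted_mean(self):
        from gccea.epidemiology import PopulationWeights

        weights = PopulationWeights({(50, "male"): 0.25, (51, "male"): 0.75})
        pooled = aggregate(
            {
                (50, "male"): self._result(100.0),
                (51, "male"): self._result(200.0, age=51),
            },
            weights,
        )
        assert pooled.cost == pytest.approx(175.0)

    def test_mismatched_keys(self):
        from gccea.epidemiology import PopulationWeights

        weights = PopulationWeights({(50, "male"): 1.0})
        with pytest.raises(ValueError, match="match"):
            aggregate({(51, "male"): self._result(100.0, age=51)}, weights)


class TestMonotonicity:
    def test_surveillance_gain_nondecreasing_in_odds_ratio(self, base_params):
        gains = []
        for odds_ratio in (2.4, 6.0, 12.0, 21.5):
            moved = set_param(base_params, "risk.odds_ratio", odds_ratio)
            out = evaluate_strategies(moved, subgroup=(60, "male"),
                                      strategies=("none", "surveil1y"))
            gains.append(out["surveil1y"].qaly - out["none"].qaly)
        assert all(b >= a - 1e-12 for a, b in zip(gains, gains[1:]))

    def test_surveillance_gain_nondecreasing_in_prevalence(self, base_params):
        gains = []
        for prevalence in (0.065, 0.135, 0.20, 0.27):
            moved = set_param(base_params, "risk.prevalence", prevalence)
            out = evaluate_strategies(moved, subgroup=(60, "male"),
                                      strategies=("none", "surveil1y"))
            gains.append(out["surveil1y"].qaly - out["none"].qaly)
        assert all(b >= a - 1e-12 for a, b in zip(gains, gains[1:]))

    def test_surveillance_gain_nonincreasing_in_discount(self, base_params):
        gains = []
        for rate in (0.0, 0.03, 0.05):
            moved = set_param(base_params, "econ.discount_rate", rate)
            out = evaluate_strategies(moved, subgroup=(60, "male"),
                                      strategies=("none", "surveil1y"))
            gains.append(out["surveil1y"].qaly - out["none"].qaly)
        assert all(b <= a + 1e-12 for a, b in zip(gains, gains[1:]))
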