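"""Cost/QALY accrual, discounting, and incremental summaries."""

import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2dcem.cohort_engine import run_cohort
from t2dcem.economics import (
    accrue_complication_costs,
    accrue_hypoglycemia,
    annual_treatment_cost,
    build_ledger,
    classify_increments,
    discount_stream,
    increment,
    summarize_ce,
    utility_for_cycle,
)
from t2dcem.parameters import ComplicationCostEntry, ValueSE
from t2dcem.risk_equations import hba1c_trajectory
from t2dcem.synthetic_data import make_toy_submodel

from conftest import make_config


class TestAnnualTreatmentCost:
    def test_comparator_matches_printed_total(self, paper_config):
        cost = annual_treatment_cost(paper_config.arm_comparator, 365.25)
        assert cost == pytest.approx(47.3 * 365.25)
        assert abs(cost - 17277) <= 2  # printed annual total, +/-2 CNY rounding

    def test_zero_costs(self, paper_config):
        strategy = copy.deepcopy(paper_config.arm_intervention)
        strategy.drug_cost_daily = 0.0
        strategy.needle_cost_daily = 0.0
        strategy.smbg_cost_daily = 0.0
        assert annual_treatment_cost(strategy, 365.25) == 0.0

    def test_intervention_arithmetic(self, paper_config):
        cost = annual_treatment_cost(paper_config.arm_intervention, 365.25)
        assert cost == pytest.approx(37.6 * 365.25)  # 13,733.4


class TestDiscounting:
    def test_zero_rate_is_sum(self):
        stream = np.array([10.0, 20.0, 30.0])
        assert discount_stream(stream, 0.0) == pytest.approx(60.0)

    def test_single_deferred_payment(self):
        assert discount_stream(np.array([0.0, 100.0]), 0.05) == pytest.approx(
            100.0 / 1.05
        )

    def test_monotone_in_rate(self):
        stream = np.array([50.0, 50.0, 50.0])
        pvs = [discount_stream(stream, r) for r in (0.0, 0.02, 0.05, 0.1)]
        assert all(a > b for a, b in zip(pvs, pvs[1:]))

    def test_from_cycle_one_convention(self):
        assert discount_stream(
            np.array([100.0]), 0.05, from_cycle_one=True
        ) == pytest.approx(100.0 / 1.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_stream(np.array([1.0]), -0.01)


class TestComplicationCosts:
    def test_event_plus_state_cost_on_entry(self):
        # whole cohort enters the absorbing state in cycle 0
        toy = make_toy_submodel(2, 1.0)
        config = make_config([toy.spec], toy.equations, horizon=3)
        result = run_cohort(config, "comparator")
        entry = ComplicationCostEntry(
            toy.spec.states[1], event_cost=158396, state_cost=127391
        )
        streams = accrue_complication_costs(result, {toy.spec.states[1]: entry})
        stream = streams[toy.spec.states[1]]
        assert stream[0] == pytest.approx(158396 + 127391)
        assert stream[1] == pytest.approx(127391)  # state cost only afterwards

    def test_occupancy_only(self):
        toy = make_toy_submodel(2, 0.5)
        config = make_config([toy.spec], toy.equations, horizon=1)
        result = run_cohort(config, "comparator")
        entry = ComplicationCostEntry(toy.spec.states[1], 0.0, 2163.0)
        stream = accrue_complication_costs(result, {toy.spec.states[1]: entry})
        assert stream[toy.spec.states[1]][0] == pytest.approx(0.5 * 2163)

    def test_missing_state_errors(self, paper_results):
        entry = ComplicationCostEntry("narnia", 1.0, 1.0)
        with pytest.raises(KeyError, match="narnia"):
            accrue_complication_costs(
                paper_results["comparator"], {"narnia": entry}
            )


class TestHypoglycemia:
    def _streams(self, paper_config, ns, sev, alive=1.0):
        strategy = copy.deepcopy(paper_config.arm_intervention)
        strategy.hypo_nonsevere_rate = ns
        strategy.hypo_severe_rate = sev
        path = hba1c_trajectory(strategy, 0.0, paper_config.switch_rule, 1)
        return accrue_hypoglycemia(
            path, np.array([alive]), paper_config.hypo_costs, paper_config.utilities
        )

    def test_zero_rates(self, paper_config):
        cost, dis = self._streams(paper_config, 0.0, 0.0)
        assert cost[0] == 0.0 and dis[0] == 0.0

    def test_worked_example(self, paper_config):
        cost, dis = self._streams(paper_config, 0.06, 0.0)
        assert cost[0] == pytest.approx(52.8)
        assert dis[0] == pytest.approx(-0.00084)

    def test_linearity(self, paper_config):
        c1, d1 = self._streams(paper_config, 0.06, 0.01)
        c2, d2 = self._streams(paper_config, 0.12, 0.02)
        assert c2[0] == pytest.approx(2 * c1[0])
        assert d2[0] == pytest.approx(2 * d1[0])


class TestUtilityForCycle:
    def test_baseline_profile(self, paper_config):
        value = utility_for_cycle(
            {}, 1.0, paper_config.utilities, bmi=35.9, injections_per_day=0
        )
        assert value == pytest.approx(0.936)

    def test_heart_failure_decrement(self, paper_config):
        value = utility_for_cycle(
            {"hf": 1.0}, 1.0, paper_config.utilities, bmi=35.9, injections_per_day=0
        )
        assert value == pytest.approx(0.936 - 0.186)

    def test_age_and_duration_progression(self, paper_config):
        base = utility_for_cycle({}, 1.0, paper_config.utilities, bmi=35.9)
        aged = utility_for_cycle(
            {}, 1.0, paper_config.utilities, age_delta=10.0, duration_delta=10.0,
            bmi=35.9,
        )
        assert base - aged == pytest.approx(0.024 + 0.016)

    def test_floor_at_zero(self, paper_config):
        value = utility_for_cycle(
            {"hf": 1.0, "stroke": 1.0, "esrd": 1.0, "amputation": 1.0},
            0.05,
            paper_config.utilities,
            age_delta=60.0,
            bmi=35.9,
        )
        assert value >= 0.0

    def test_injection_disutility(self, paper_config):
        one = utility_for_cycle(
            {}, 1.0, paper_config.utilities, bmi=35.9, injections_per_day=1
        )
        assert 0.936 - one == pytest.approx(0.00805)


class TestLedger:
    def test_category_sum_equals_total(self, paper_ledgers):
        for ledger in paper_ledgers.values():
            total = ledger.total_cost_stream
            summed = np.zeros_like(total)
            for stream in ledger.categories.values():
                summed = summed + stream
            np.testing.assert_allclose(summed, total, atol=1e-6)

    def test_discounted_leq_undiscounted(self, paper_ledgers):
        for ledger in paper_ledgers.values():
            assert ledger.total_cost_discounted <= ledger.total_cost_undiscounted
            disc = ledger.discounted_category_totals()
            undisc = ledger.undiscounted_category_totals()
            for cat in disc:
                assert disc[cat] <= undisc[cat] + 1e-9

    def test_cost_linearity_in_catalog(self, paper_config):
        k = 3.0
        scaled = copy.deepcopy(paper_config)
        for entry in scaled.costs.values():
            entry.event_cost *= k
            entry.state_cost *= k
        scaled.background_cost.mean *= k
        for entry in scaled.hypo_costs.values():
            entry.mean *= k
        for strategy in (scaled.arm_intervention, scaled.arm_comparator,
                         scaled.switch_rule.post_switch_strategy):
            strategy.drug_cost_daily *= k
            strategy.needle_cost_daily *= k
            strategy.smbg_cost_daily *= k
            strategy.drug_cost_components = None
        base = build_ledger(run_cohort(paper_config, "comparator"), paper_config)
        big = build_ledger(run_cohort(scaled, "comparator"), scaled)
        assert big.total_cost_discounted == pytest.approx(
            k * base.total_cost_discounted
        )

    def test_zero_discount_limit(self, paper_config):
        paper_config.econ.discount_rate_cost = 0.0
        paper_config.econ.discount_rate_qaly = 0.0
        ledger = build_ledger(run_cohort(paper_config, "comparator"), paper_config)
        assert ledger.total_cost_discounted == pytest.approx(
            ledger.total_cost_undiscounted
        )
        assert ledger.qalys_discounted == pytest.approx(float(ledger.qalys.sum()))

    def test_zero_model_only_background(self):
        toy = make_toy_submodel(2, 0.0)
        config = make_config([toy.spec], toy.equations, horizon=5)
        config.background_cost = ValueSE(1000.0, None)
        ledger = build_ledger(run_cohort(config, "comparator"), config)
        assert ledger.categories["background"].sum() == pytest.approx(5000.0)
        assert ledger.total_cost_undiscounted == pytest.approx(5000.0)


class TestSummaries:
    def test_increment_worked_examples(self):
        assert increment(5.685, 5.249) == pytest.approx(0.436)
        assert increment(412494, 446748) == pytest.approx(-34254)
        assert round(increment(10.824, 10.781), 3) == pytest.approx(0.043)

    def test_paper_config_dominant(self, paper_ce):
        assert paper_ce.delta_qaly > 0
        assert paper_ce.delta_cost < 0
        assert paper_ce.verdict == "dominant"
        assert paper_ce.icer is None
        assert paper_ce.nmb > 0

    def test_equivalent_degenerate(self):
        assert classify_increments(0.0, 0.0) == ("equivalent", None)

    def test_icer_case(self):
        verdict, icer = classify_increments(1000.0, 0.5)
        assert verdict == "icer"
        assert icer == pytest.approx(2000.0)

    def test_mismatched_horizons(self, paper_config, paper_ledgers):
        short = copy.deepcopy(paper_config)
        short.econ.horizon_years = 5
        ledger = build_ledger(run_cohort(short, "intervention"), short)
        with pytest.raises(ValueError, match="horizon"):
            summarize_ce(ledger, paper_ledgers["comparator"], paper_config.econ)

    @settings(max_examples=200, deadline=None)
    @given(
        d_cost=st.floats(-1e6, 1e6, allow_nan=False),
        d_qaly=st.floats(-10, 10, allow_nan=False),
    )
    def test_classification_matches_quadrant_oracle(self, d_cost, d_qaly):
        verdict, icer = classify_increments(d_cost, d_qaly)
        # brute-force four-quadrant check
        if d_cost < 0 and d_qaly > 0:
            assert verdict == "dominant"
        elif d_cost > 0 and d_qaly < 0:
            assert verdict == "dominated"
        elif d_qaly == 0:
            assert verdict == ("equivalent" if d_cost == 0 else "undefined")
        else:
            assert verdict == "icer"
            assert icer == pytest.approx(d_cost / d_qaly)


class TestHalfCycleFlag:
    def test_half_cycle_increases_life_years(self, paper_config):
        base = build_ledger(run_cohort(paper_config, "comparator"), paper_config)
        hc_config = copy.deepcopy(paper_config)
        hc_config.econ.half_cycle_correction = True
        hc = build_ledger(run_cohort(hc_config, "comparator"), hc_config)
        # survival declines, so averaging start/end of cycle adds exposure
        assert hc.life_years_discounted > base.life_years_discounted
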