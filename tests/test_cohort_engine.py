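"""Cohort propagation: oracle equivalence, conservation, reporting helpers."""

import copy
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from t2dcem.cohort_engine import (
    MarkovSubModelSpec,
    StateOccupancy,
    Transition,
    build_transition_probabilities,
    cumulative_incidence,
    percent_reduction,
    propagate_cycle,
    relative_risk,
    run_cohort,
)
from t2dcem.risk_equations import CovariateVector, RiskEquationSpec
from t2dcem.synthetic_data import make_toy_submodel, toy_occupancy_by_powering

from conftest import make_config

COV = CovariateVector(
    age=60, female=0.5, smoker=0.2, duration=10, hba1c_pct=7.0, sbp=120,
    dbp=80, bmi=30, tc=4.5, ldl=2.5, hdl=1.2, tg=1.8, heart_rate=70,
    wbc=6.0, egfr=80,
)


def _propagate_toy(toy, cycles):
    specs = {toy.spec.submodel_id: toy.spec}
    occ = StateOccupancy.initial([toy.spec])
    transitions = {
        toy.spec.submodel_id: build_transition_probabilities(
            toy.spec, COV, toy.equations
        )
    }
    out = [occ]
    for _ in range(cycles):
        occ, _inc = propagate_cycle(occ, transitions, specs)
        out.append(occ)
    return out


class TestSubModelSpec:
    def test_backward_transition_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            MarkovSubModelSpec(
                "bad", ["a", "b"], [Transition("b", "a", "eq")]
            )

    def test_duplicate_states_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MarkovSubModelSpec("bad", ["a", "a"], [])


class TestBuildTransitionProbabilities:
    def test_zero_rates_identity(self):
        toy = make_toy_submodel(3, 0.0)
        probs = build_transition_probabilities(toy.spec, COV, toy.equations)
        assert all(p == 0.0 for outs in probs.values() for _, p in outs)

    def test_renormalization_with_warning(self, caplog):
        spec = MarkovSubModelSpec(
            "comp",
            ["a", "b", "c"],
            [Transition("a", "b", "p7"), Transition("a", "c", "p6")],
        )
        eqs = {
            "p7": RiskEquationSpec("p7", "constant_prob", 0.7),
            "p6": RiskEquationSpec("p6", "constant_prob", 0.6),
        }
        with caplog.at_level(logging.WARNING):
            probs = build_transition_probabilities(spec, COV, eqs)
        total = sum(p for _, p in probs["a"])
        assert total == pytest.approx(1.0)
        assert probs["a"][0][1] == pytest.approx(0.7 / 1.3)
        assert any("renormaliz" in rec.message for rec in caplog.records)

    def test_three_state_chain_matches_hand_matrix(self):
        toy = make_toy_submodel(3, 0.25)
        occ = _propagate_toy(toy, 5)[-1]
        expected = toy_occupancy_by_powering(toy, 5)
        np.testing.assert_allclose(
            occ.masses[toy.spec.submodel_id], expected, atol=1e-12
        )


class TestPropagateCycle:
    def test_identity_transitions(self):
        toy = make_toy_submodel(2, 0.0)
        occs = _propagate_toy(toy, 10)
        for occ in occs:
            np.testing.assert_array_equal(
                occ.masses[toy.spec.submodel_id], [1.0, 0.0]
            )

    def test_two_state_closed_form(self):
        toy = make_toy_submodel(2, 0.3)
        occ = _propagate_toy(toy, 3)[-1]
        np.testing.assert_allclose(
            occ.masses[toy.spec.submodel_id], [0.7**3, 1 - 0.7**3], atol=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(
        n_states=st.integers(2, 4),
        leave=st.floats(0.0, 1.0),
        p_death=st.floats(0.0, 1.0),
        cycles=st.integers(1, 20),
    )
    def test_mass_conservation(self, n_states, leave, p_death, cycles):
        toy = make_toy_submodel(n_states, leave)
        specs = {toy.spec.submodel_id: toy.spec}
        occ = StateOccupancy.initial([toy.spec])
        transitions = {
            toy.spec.submodel_id: build_transition_probabilities(
                toy.spec, COV, toy.equations
            )
        }
        for _ in range(cycles):
            occ, _ = propagate_cycle(occ, transitions, specs, p_death=p_death)
            assert abs(occ.alive + occ.dead - 1.0) < 1e-10
            assert abs(occ.masses[toy.spec.submodel_id].sum() - occ.alive) < 1e-10


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_states", [2, 3, 4])
    @pytest.mark.parametrize("leave", [0.0, 0.05, 0.3, 0.77, 1.0])
    def test_matches_matrix_powering_100_cycles(self, n_states, leave):
        toy = make_toy_submodel(n_states, leave)
        occs = _propagate_toy(toy, 100)
        for cycle in (0, 1, 2, 5, 17, 50, 100):
            np.testing.assert_allclose(
                occs[cycle].masses[toy.spec.submodel_id],
                toy_occupancy_by_powering(toy, cycle),
                atol=1e-9,
            )

    def test_run_cohort_matches_oracle(self):
        toy = make_toy_submodel(4, 0.2)
        config = make_config([toy.spec], toy.equations, horizon=40)
        result = run_cohort(config, "comparator")
        for t in range(40):
            expected = toy_occupancy_by_powering(toy, t + 1)
            actual = [result.occupancy[s][t] for s in toy.spec.states]
            np.testing.assert_allclose(actual, expected, atol=1e-9)


class TestRunCohort:
    def test_zero_hazards(self):
        toy = make_toy_submodel(3, 0.0)
        config = make_config([toy.spec], toy.equations, horizon=10)
        result = run_cohort(config, "intervention")
        assert result.cumulative_mortality == 0.0
        for state in toy.spec.states[1:]:
            assert cumulative_incidence(result, state) == 0.0

    def test_deterministic(self, paper_config):
        r1 = run_cohort(paper_config, "comparator")
        r2 = run_cohort(paper_config, "comparator")
        np.testing.assert_array_equal(r1.alive, r2.alive)
        for s in r1.incidence:
            np.testing.assert_array_equal(r1.incidence[s], r2.incidence[s])

    def test_survival_non_increasing(self, paper_results):
        for result in paper_results.values():
            assert np.all(np.diff(result.alive) <= 1e-15)

    def test_cumulative_incidence_monotone(self, paper_results):
        for result in paper_results.values():
            for state, inc in result.incidence.items():
                cum = np.cumsum(inc)
                assert np.all(np.diff(cum) >= -1e-15), state

    def test_mortality_equals_one_minus_alive(self, paper_results):
        for result in paper_results.values():
            assert result.cumulative_mortality == pytest.approx(
                1.0 - result.alive[-1], abs=1e-10
            )

    def test_bad_arm(self, paper_config):
        with pytest.raises(ValueError, match="arm"):
            run_cohort(paper_config, "placebo")

    def test_horizon_over_40(self, paper_config):
        paper_config.econ.horizon_years = 45
        with pytest.raises(ValueError, match="40"):
            run_cohort(paper_config, "comparator")

    def test_invariants_at_every_cycle(self, paper_results):
        for result in paper_results.values():
            for occ in result.trace:
                assert abs(occ.alive + occ.dead - 1.0) < 1e-10


EYE_RENAL_NEURO = (
    "bdr", "pdr", "me", "pdr_me", "svl",
    "microalbuminuria", "macroalbuminuria", "esrd", "neuropathy",
)


class TestDominanceDirection:
    def test_intervention_lower_incidence(self, paper_results):
        ri, rc = paper_results["intervention"], paper_results["comparator"]
        for state in EYE_RENAL_NEURO:
            assert cumulative_incidence(ri, state) < cumulative_incidence(rc, state)

    def test_intervention_lower_mortality(self, paper_results):
        assert (
            paper_results["intervention"].cumulative_mortality
            < paper_results["comparator"].cumulative_mortality
        )

    def test_direction_reverses_when_hba1c_swapped(self, paper_config):
        swapped = copy.deepcopy(paper_config)
        swapped.arm_intervention.hba1c_on_treatment = (
            paper_config.arm_comparator.hba1c_on_treatment
        )
        swapped.arm_comparator.hba1c_on_treatment = (
            paper_config.arm_intervention.hba1c_on_treatment
        )
        ri = run_cohort(swapped, "intervention")
        rc = run_cohort(swapped, "comparator")
        for state in EYE_RENAL_NEURO:
            assert cumulative_incidence(ri, state) > cumulative_incidence(rc, state)


class TestReportingHelpers:
    def test_relative_risk_rounding(self):
        assert relative_risk(26.32, 34.81) == 0.76
        assert relative_risk(2.27, 3.86) == 0.59

    def test_relative_risk_identity(self):
        assert relative_risk(5.5, 5.5) == 1.00

    def test_relative_risk_zero_comparator(self):
        with pytest.raises(ZeroDivisionError):
            relative_risk(1.0, 0.0)

    def test_percent_reduction(self):
        assert percent_reduction(10.41, 14.05) == 25.9
        assert percent_reduction(26.32, 34.81) == 24.4

    def test_cumulative_incidence_toy(self):
        toy = make_toy_submodel(2, 0.3)
        config = make_config([toy.spec], toy.equations, horizon=3)
        result = run_cohort(config, "comparator")
        assert cumulative_incidence(result, toy.spec.states[1]) == pytest.approx(
            65.7, abs=1e-9
        )

    def test_cumulative_incidence_unknown_state(self, paper_results):
        with pytest.raises(KeyError):
            cumulative_incidence(paper_results["comparator"], "narnia")

    def test_to_frame_tidy(self, paper_results):
        frame = paper_results["comparator"].to_frame()
        assert set(frame.columns) == {
            "cycle", "arm", "submodel", "state", "occupancy",
            "incident_probability",
        }
        horizon = paper_results["comparator"].horizon
        n_states = sum(len(s) for s in paper_results["comparator"].states.values())
        assert len(frame) == horizon * n_states
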