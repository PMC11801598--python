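"""Programmatic test fixtures: toy sub-models with closed-form occupancy,
perturbed configurations, and synthetic parameter catalogs.

Everything here is generated at call time (seeded where random); nothing is
checked into the repository.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_engine import MarkovSubModelSpec, Transition
from .parameters import ModelConfig, ValueSE
from .risk_equations import RiskEquationSpec

__all__ = [
    "ToySubModel",
    "make_toy_submodel",
    "perturb_config",
    "emulate_parameter_catalog",
]

logger = logging.getLogger(__name__)


@dataclass
class ToySubModel:
    """A pure forward chain with one constant leave probability per state.

    Because every non-terminal state leaves with the same probability, the
    number of forward jumps after t cycles is Binomial(t, p) truncated at
    the final absorbing state — giving an exact closed-form occupancy.
    """

    spec: MarkovSubModelSpec
    equations: dict[str, RiskEquationSpec]
    leave_prob: float

    def occupancy(self, cycle: int) -> np.ndarray:
        """Exact occupancy after ``cycle`` cycles (cycle 0 = initial state)."""
        n = len(self.spec.states)
        p = self.leave_prob
        out = np.zeros(n)
        if cycle == 0:
            out[0] = 1.0
            return out
        pmf = stats.binom.pmf(np.arange(n - 1), cycle, p)
        out[: n - 1] = pmf
        out[n - 1] = 1.0 - pmf.sum()
        return out


def make_toy_submodel(
    n_states: int, leave_prob: float, seed: int | None = None
) -> ToySubModel:
    """Build a toy chain loadable by the cohort engine plus its exact oracle.

    ``seed`` only randomizes the sub-model's name (fixtures built in a loop
    stay distinguishable); the dynamics are fully determined by the inputs.
    """
    if not 2 <= n_states <= 4:
        raise ValueError("n_states must be within [2, 4]")
    if not 0.0 <= leave_prob <= 1.0:
        raise ValueError("leave_prob must be within [0, 1]")
    suffix = "" if seed is None else f"_{np.random.default_rng(seed).integers(1e6)}"
    sm_id = f"toy{suffix}"
    states = [f"{sm_id}_s{i}" for i in range(n_states)]
    eq_id = f"{sm_id}_leave"
    transitions = [
        Transition(states[i], states[i + 1], eq_id) for i in range(n_states - 1)
    ]
    spec = MarkovSubModelSpec(submodel_id=sm_id, states=states, transitions=transitions)
    equations = {
        eq_id: RiskEquationSpec(
            equation_id=eq_id, form="constant_prob", intercept=float(leave_prob)
        )
    }
    return ToySubModel(spec=spec, equations=equations, leave_prob=float(leave_prob))


_FRACTION_PATHS = ("prop_female", "prop_smoker")


def perturb_config(
    config: ModelConfig, relative_spread: float, seed: int
) -> ModelConfig:
    """Multiply every numeric leaf by an independent factor in [1-s, 1+s].

    The result is clamped back into feasible ranges where needed (with a log
    entry) and passes validation.
    """
    if relative_spread < 0:
        raise ValueError("relative_spread must be >= 0")
    rng = np.random.default_rng(seed)
    new = copy.deepcopy(config)

    def factor() -> float:
        return float(rng.uniform(1.0 - relative_spread, 1.0 + relative_spread))

    def clamp(value: float, lo: float, hi: float, where: str) -> float:
        clamped = min(max(value, lo), hi)
        if clamped != value:
            logger.info("perturb_config: clamped %s to %s", where, clamped)
        return clamped

    cohort = new.cohort
    for name in (
        "age_years", "duration_years", "hba1c_pct", "sbp_mmHg", "dbp_mmHg",
        "tc_mmol", "ldl_mmol", "hdl_mmol", "tg_mmol", "bmi", "heart_rate_bpm",
        "wbc", "egfr",
    ):
        setattr(cohort, name, getattr(cohort, name) * factor())
    for name in _FRACTION_PATHS:
        setattr(
            cohort,
            name,
            clamp(getattr(cohort, name) * factor(), 0.0, 1.0, f"cohort.{name}"),
        )
    cohort.age_years = clamp(
        cohort.age_years, 1.0, 120.0 - new.econ.horizon_years, "cohort.age_years"
    )

    for strategy in (
        new.arm_intervention,
        new.arm_comparator,
        new.switch_rule.post_switch_strategy,
    ):
        for name in (
            "hba1c_on_treatment", "bmi_on_treatment", "sbp_on_treatment",
            "dbp_on_treatment", "hypo_nonsevere_rate", "hypo_severe_rate",
            "needle_cost_daily", "smbg_cost_daily",
        ):
            setattr(strategy, name, getattr(strategy, name) * factor())
        drug_factor = factor()
        strategy.drug_cost_daily *= drug_factor
        if strategy.drug_cost_components is not None:
            # keep the component breakdown consistent with the scaled total
            strategy.drug_cost_components = [
                c * drug_factor for c in strategy.drug_cost_components
            ]
    new.switch_rule.hba1c_threshold_pct *= factor()
    new.hba1c_drift_per_year *= factor()

    for entry in new.costs.values():
        entry.event_cost *= factor()
        entry.state_cost *= factor()
    new.background_cost.mean *= factor()
    for entry in new.hypo_costs.values():
        entry.mean *= factor()

    util = new.utilities
    util.baseline.mean = clamp(
        util.baseline.mean * factor(), 1e-6, 1.0, "utilities.baseline"
    )
    for entry in util.state_decrements.values():
        entry.mean = clamp(entry.mean * factor(), -1.0, 0.0, "utilities.states")
    for name in ("age_per_10_years", "female", "duration_per_10_years",
                 "bmi_per_unit", "hypo_nonsevere", "hypo_severe"):
        entry = getattr(util, name)
        entry.mean = clamp(entry.mean * factor(), -1.0, 0.0, f"utilities.{name}")
    for entry in util.injections.values():
        entry.mean = clamp(entry.mean * factor(), -1.0, 0.0, "utilities.injections")

    new.validate()
    return new


def emulate_parameter_catalog(
    n_states: int, n_costs: int, seed: int
) -> tuple[dict[str, ValueSE], dict[str, dict[str, float]]]:
    """Synthetic utility and cost catalogs shaped like the bundled tables.

    Utilities: baseline in (0.8, 1.0) and decrements in (-0.2, 0) with
    |SE| = |decrement|/10, which keeps every row beta-feasible; costs:
    event/state costs log-uniform on [1e2, 1e5] with 10% SE, always
    gamma-feasible.
    """
    if n_states < 1 or n_costs < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    utilities: dict[str, ValueSE] = {
        "baseline": ValueSE(mean=float(rng.uniform(0.8, 1.0)), se=0.05)
    }
    for i in range(n_states):
        dec = float(rng.uniform(-0.2, -1e-4))
        utilities[f"syn_state_{i}"] = ValueSE(mean=dec, se=abs(dec) / 10.0)
    costs: dict[str, dict[str, float]] = {}
    for i in range(n_costs):
        event = float(10 ** rng.uniform(2.0, 5.0))
        state = float(10 ** rng.uniform(2.0, 5.0))
        costs[f"syn_cost_{i}"] = {
            "event_cost": event,
            "event_cost_se": 0.1 * event,
            "state_cost": state,
            "state_cost_se": 0.1 * state,
        }
    return utilities, costs


def toy_occupancy_by_powering(toy: ToySubModel, cycle: int) -> np.ndarray:
    """Independent oracle: brute-force transition-matrix powering."""
    n = len(toy.spec.states)
    matrix = np.zeros((n, n))
    for i in range(n - 1):
        matrix[i, i] = 1.0 - toy.leave_prob
        matrix[i, i + 1] = toy.leave_prob
    matrix[n - 1, n - 1] = 1.0
    start = np.zeros(n)
    start[0] = 1.0
    return start @ np.linalg.matrix_power(matrix, cycle)
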