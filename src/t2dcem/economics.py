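"""Cost and QALY accrual, discounting, and incremental cost-effectiveness.

Cost convention: an event cost is charged once, in the cycle the transition
occurs; a state cost is charged for every cycle spent in the state
including the event cycle.  Utilities combine additively (baseline plus
decrements) with a floor at zero.  Death contributes neither cost nor QALY
from its cycle of occurrence onward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .cohort_engine import SimulationResult

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import (
        ComplicationCostEntry,
        EconomicSettings,
        ModelConfig,
        TreatmentStrategy,
        UtilityCatalog,
        ValueSE,
    )
    from .risk_equations import RiskFactorPath

__all__ = [
    "EconomicLedger",
    "CEResult",
    "annual_treatment_cost",
    "accrue_complication_costs",
    "accrue_hypoglycemia",
    "utility_for_cycle",
    "discount_stream",
    "discount_factors",
    "build_ledger",
    "summarize_ce",
    "increment",
]

CATEGORY_SUM_TOL = 1e-6


def annual_treatment_cost(strategy: "TreatmentStrategy", days_per_year: float) -> float:
    """Annual glucose-lowering treatment cost: daily components x year length."""
    return strategy.total_daily_cost * days_per_year


def discount_factors(
    n: int, rate: float, from_cycle_one: bool = False
) -> np.ndarray:
    """Per-cycle discount factors.

    Default convention: the first cycle is undiscounted (divisor
    ``(1+rate)**t`` with t starting at 0); ``from_cycle_one`` shifts the
    exponent to start at 1.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.arange(n, dtype=float) + (1.0 if from_cycle_one else 0.0)
    return (1.0 + rate) ** (-t)


def discount_stream(
    stream: np.ndarray, rate: float, from_cycle_one: bool = False
) -> float:
    """Present value of a per-cycle stream."""
    stream = np.asarray(stream, dtype=float)
    return float(stream @ discount_factors(len(stream), rate, from_cycle_one))


def accrue_complication_costs(
    result: SimulationResult,
    costs: dict[str, "ComplicationCostEntry"],
    occupancy: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-state cost streams: incidence x event cost + occupancy x state cost.

    ``occupancy`` overrides the result's end-of-cycle occupancy (used for
    the half-cycle-corrected variant).
    """
    occ = occupancy if occupancy is not None else result.occupancy
    streams: dict[str, np.ndarray] = {}
    for state_id, entry in costs.items():
        if state_id not in result.incidence:
            raise KeyError(f"cost entry for unknown state {state_id!r}")
        streams[state_id] = (
            result.incidence[state_id] * entry.event_cost
            + occ[state_id] * entry.state_cost
        )
    return streams


def accrue_hypoglycemia(
    path: "RiskFactorPath",
    alive: np.ndarray,
    hypo_costs: dict[str, "ValueSE"],
    utilities: "UtilityCatalog",
) -> tuple[np.ndarray, np.ndarray]:
    """Hypoglycemia cost and (negative) QALY-decrement streams per cycle."""
    alive = np.asarray(alive, dtype=float)
    ns = path.hypo_nonsevere_rate
    sev = path.hypo_severe_rate
    cost = alive * (
        ns * hypo_costs["nonsevere"].mean + sev * hypo_costs["severe"].mean
    )
    disutility = alive * (
        ns * utilities.hypo_nonsevere.mean + sev * utilities.hypo_severe.mean
    )
    return cost, disutility


def utility_for_cycle(
    state_masses: dict[str, float],
    alive: float,
    utilities: "UtilityCatalog",
    *,
    age_delta: float = 0.0,
    duration_delta: float = 0.0,
    bmi: float | None = None,
    injections_per_day: int = 0,
) -> float:
    """Utility-weighted alive mass for one cycle (before event disutilities).

    Base utility = baseline + demographic progression decrements (per-10-year
    age and duration deltas from the baseline cohort, BMI relative to the
    catalog anchor) + injection disutility; each occupied state adds its
    additive decrement.  The result is floored at zero.
    """
    base = (
        utilities.baseline.mean
        + utilities.age_per_10_years.mean * (age_delta / 10.0)
        + utilities.duration_per_10_years.mean * (duration_delta / 10.0)
        + utilities.injection_disutility(injections_per_day)
    )
    if bmi is not None:
        base += utilities.bmi_per_unit.mean * (bmi - utilities.bmi_anchor)
    total = alive * base
    for state_id, mass in state_masses.items():
        entry = utilities.state_decrements.get(state_id)
        if entry is not None:
            total += mass * entry.mean
    return max(total, 0.0)


@dataclass
class EconomicLedger:
    """Per-cycle undiscounted streams with discounting applied on demand."""

    arm: str
    categories: dict[str, np.ndarray]  # undiscounted cost per category per cycle
    life_years: np.ndarray
    qalys: np.ndarray
    discount_rate_cost: float
    discount_rate_qaly: float
    from_cycle_one: bool = False
    state_cost_streams: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def horizon(self) -> int:
        return len(self.life_years)

    @property
    def total_cost_stream(self) -> np.ndarray:
        return np.sum(list(self.categories.values()), axis=0)

    def discounted_category_totals(self) -> dict[str, float]:
        return {
            cat: discount_stream(s, self.discount_rate_cost, self.from_cycle_one)
            for cat, s in self.categories.items()
        }

    def undiscounted_category_totals(self) -> dict[str, float]:
        return {cat: float(s.sum()) for cat, s in self.categories.items()}

    @property
    def total_cost_discounted(self) -> float:
        return discount_stream(
            self.total_cost_stream, self.discount_rate_cost, self.from_cycle_one
        )

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.total_cost_stream.sum())

    @property
    def life_years_discounted(self) -> float:
        return discount_stream(
            self.life_years, self.discount_rate_qaly, self.from_cycle_one
        )

    @property
    def qalys_discounted(self) -> float:
        return discount_stream(self.qalys, self.discount_rate_qaly, self.from_cycle_one)


def build_ledger(result: SimulationResult, config: "ModelConfig") -> EconomicLedger:
    """Turn one arm's simulation traces into per-cycle economic streams."""
    econ = config.econ
    horizon = result.horizon
    path = result.path

    if econ.half_cycle_correction:
        # effective exposure = average of start- and end-of-cycle mass
        alive_eff = 0.5 * (result.alive_start + result.alive)
        occ_eff: dict[str, np.ndarray] = {}
        for sm_id, states in result.states.items():
            for i, state in enumerate(states):
                end = result.occupancy[state]
                start = np.empty(horizon)
                start[0] = 1.0 if i == 0 else 0.0
                start[1:] = end[:-1]
                occ_eff[state] = 0.5 * (start + end)
    else:
        alive_eff = result.alive
        occ_eff = result.occupancy

    treatment = alive_eff * path.daily_treatment_cost * econ.days_per_year
    background = alive_eff * config.background_cost.mean
    hypo_cost, hypo_disutility = accrue_hypoglycemia(
        path, alive_eff, config.hypo_costs, config.utilities
    )
    state_streams = accrue_complication_costs(result, config.costs, occupancy=occ_eff)

    categories: dict[str, np.ndarray] = {
        "treatment": treatment,
        "background": background,
        "hypoglycemia": hypo_cost,
    }
    for category, states in config.cost_categories.items():
        stream = np.zeros(horizon)
        for state in states:
            stream += state_streams[state]
        categories[category] = stream

    utilities = config.utilities
    qalys = np.empty(horizon)
    for t in range(horizon):
        masses = {state: occ_eff[state][t] for state in result.occupancy}
        base = utility_for_cycle(
            masses,
            float(alive_eff[t]),
            utilities,
            age_delta=float(t),
            duration_delta=float(t),
            bmi=float(path.bmi[t]),
            injections_per_day=int(path.injections_per_day[t]),
        )
        qalys[t] = max(base + hypo_disutility[t], 0.0)

    return EconomicLedger(
        arm=result.arm,
        categories=categories,
        life_years=alive_eff.astype(float).copy(),
        qalys=qalys,
        discount_rate_cost=econ.discount_rate_cost,
        discount_rate_qaly=econ.discount_rate_qaly,
        from_cycle_one=econ.discount_from_cycle_one,
        state_cost_streams=state_streams,
    )


def increment(intervention: float, comparator: float) -> float:
    """Incremental value, intervention minus comparator."""
    return intervention - comparator


@dataclass
class CEResult:
    """Incremental cost-effectiveness summary for two arms."""

    life_years: dict[str, float]
    qalys: dict[str, float]
    costs_total: dict[str, float]
    costs_by_category: dict[str, dict[str, float]]
    delta_cost: float
    delta_qaly: float
    delta_life_years: float
    verdict: str  # dominant | dominated | icer | equivalent | undefined
    icer: float | None
    nmb: float
    wtp: float

    @property
    def verdict_label(self) -> str:
        if self.verdict == "icer":
            return f"{self.icer:,.0f}"
        return self.verdict


def classify_increments(delta_cost: float, delta_qaly: float) -> tuple[str, float | None]:
    """Dominance classification of an (increment cost, increment QALY) pair."""
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant", None
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated", None
    if delta_qaly == 0:
        return ("equivalent", None) if delta_cost == 0 else ("undefined", None)
    return "icer", delta_cost / delta_qaly


def summarize_ce(
    int_ledger: EconomicLedger,
    comp_ledger: EconomicLedger,
    econ: "EconomicSettings",
) -> CEResult:
    if int_ledger.horizon != comp_ledger.horizon:
        raise ValueError("ledgers span different horizons")
    ly = {
        "intervention": int_ledger.life_years_discounted,
        "comparator": comp_ledger.life_years_discounted,
    }
    qa = {
        "intervention": int_ledger.qalys_discounted,
        "comparator": comp_ledger.qalys_discounted,
    }
    cost = {
        "intervention": int_ledger.total_cost_discounted,
        "comparator": comp_ledger.total_cost_discounted,
    }
    by_cat = {
        "intervention": int_ledger.discounted_category_totals(),
        "comparator": comp_ledger.discounted_category_totals(),
    }
    d_cost = increment(cost["intervention"], cost["comparator"])
    d_qaly = increment(qa["intervention"], qa["comparator"])
    d_ly = increment(ly["intervention"], ly["comparator"])
    verdict, icer = classify_increments(d_cost, d_qaly)
    nmb = econ.wtp_threshold * d_qaly - d_cost
    return CEResult(
        life_years=ly,
        qalys=qa,
        costs_total=cost,
        costs_by_category=by_cat,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_life_years=d_ly,
        verdict=verdict,
        icer=icer,
        nmb=nmb,
        wtp=econ.wtp_threshold,
    )
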