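"""Deterministic cohort propagation through parallel complication sub-models.

Each sub-model is a small forward-only state chain; the cohort's probability
mass moves through all chains in parallel, linked only through shared
covariates (including expected event-history fractions) and shared
mortality.  Within a cycle, mortality is applied first and survivors then
undergo sub-model transitions; incident events are credited to the cycle of
the transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .risk_equations import (
    CovariateVector,
    RiskEquationSpec,
    annual_event_probability,
    hba1c_trajectory,
)

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ModelConfig
    from .risk_equations import RiskFactorPath

__all__ = [
    "Transition",
    "MarkovSubModelSpec",
    "StateOccupancy",
    "SimulationResult",
    "ModelStructureError",
    "build_transition_probabilities",
    "propagate_cycle",
    "run_cohort",
    "cumulative_incidence",
    "relative_risk",
    "percent_reduction",
]

logger = logging.getLogger(__name__)

MASS_TOL = 1e-10

ARMS = ("intervention", "comparator")


class ModelStructureError(ValueError):
    """A sub-model specification or composed probability is invalid."""


@dataclass(frozen=True)
class Transition:
    from_state: str
    to_state: str
    equation_id: str


@dataclass
class MarkovSubModelSpec:
    """Ordered state chain with forward-only transitions.

    State order encodes non-decreasing severity: every allowed transition
    must go strictly forward in the state list, which makes the graph
    acyclic apart from implicit self-loops (stay probabilities).
    """

    submodel_id: str
    states: list[str]
    transitions: list[Transition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.states:
            raise ModelStructureError(f"submodel {self.submodel_id!r}: no states")
        if len(set(self.states)) != len(self.states):
            raise ModelStructureError(
                f"submodel {self.submodel_id!r}: duplicate states"
            )
        index = {s: i for i, s in enumerate(self.states)}
        for tr in self.transitions:
            if tr.from_state not in index:
                raise ModelStructureError(
                    f"submodel {self.submodel_id!r}: unknown state {tr.from_state!r}"
                )
            if tr.to_state not in index:
                raise ModelStructureError(
                    f"submodel {self.submodel_id!r}: unknown state {tr.to_state!r}"
                )
            if index[tr.to_state] <= index[tr.from_state]:
                raise ModelStructureError(
                    f"submodel {self.submodel_id!r}: transition "
                    f"{tr.from_state!r}->{tr.to_state!r} is not severity-increasing"
                )

    @property
    def entry_state(self) -> str:
        return self.states[0]


@dataclass
class StateOccupancy:
    """Probability mass over every sub-model's states plus alive/dead split."""

    masses: dict[str, np.ndarray]
    alive: float
    dead: float
    dead_cv: float = 0.0

    def validate(self, specs: dict[str, MarkovSubModelSpec]) -> None:
        if abs(self.alive + self.dead - 1.0) > MASS_TOL:
            raise ModelStructureError(
                f"alive + dead = {self.alive + self.dead} != 1"
            )
        for sm_id, mass in self.masses.items():
            if np.any(mass < -MASS_TOL):
                raise ModelStructureError(f"negative mass in submodel {sm_id!r}")
            if abs(mass.sum() - self.alive) > MASS_TOL:
                raise ModelStructureError(
                    f"submodel {sm_id!r} mass {mass.sum()} != alive {self.alive}"
                )

    def copy(self) -> "StateOccupancy":
        return StateOccupancy(
            masses={k: v.copy() for k, v in self.masses.items()},
            alive=self.alive,
            dead=self.dead,
            dead_cv=self.dead_cv,
        )

    @classmethod
    def initial(cls, specs: list[MarkovSubModelSpec]) -> "StateOccupancy":
        masses = {}
        for spec in specs:
            m = np.zeros(len(spec.states))
            m[0] = 1.0
            masses[spec.submodel_id] = m
        return cls(masses=masses, alive=1.0, dead=0.0)


def build_transition_probabilities(
    spec: MarkovSubModelSpec,
    cov: CovariateVector,
    equations: dict[str, RiskEquationSpec],
) -> dict[str, list[tuple[str, float]]]:
    """Per-state outgoing probabilities (stay probability implicit).

    Competing exits whose raw probabilities sum above 1 are proportionally
    renormalized (logged); a negative composed probability is an error.
    """
    out: dict[str, list[tuple[str, float]]] = {s: [] for s in spec.states}
    for tr in spec.transitions:
        eq = equations.get(tr.equation_id)
        if eq is None:
            raise ModelStructureError(
                f"submodel {spec.submodel_id!r}: unknown equation {tr.equation_id!r}"
            )
        p = annual_event_probability(eq, cov)
        if p < 0.0 or p > 1.0 or not np.isfinite(p):
            raise ModelStructureError(
                f"equation {tr.equation_id!r} produced invalid probability {p}"
            )
        out[tr.from_state].append((tr.to_state, p))
    for state, exits in out.items():
        total = sum(p for _, p in exits)
        if total > 1.0:
            logger.warning(
                "submodel %s state %s: competing exit probabilities sum to %.4f; "
                "renormalizing proportionally",
                spec.submodel_id,
                state,
                total,
            )
            out[state] = [(to, p / total) for to, p in exits]
    return out


def propagate_cycle(
    occ: StateOccupancy,
    transitions: dict[str, dict[str, list[tuple[str, float]]]],
    specs: dict[str, MarkovSubModelSpec],
    p_death: float = 0.0,
    cv_fraction: float = 0.0,
) -> tuple[StateOccupancy, dict[str, float]]:
    """One cycle: apply mortality, then sub-model transitions.

    Returns the end-of-cycle occupancy and the incident mass that flowed
    into each state this cycle (among survivors).
    """
    if not 0.0 <= p_death <= 1.0:
        raise ModelStructureError(f"invalid death probability {p_death}")
    deaths = occ.alive * p_death
    alive = occ.alive - deaths
    new = StateOccupancy(
        masses={},
        alive=alive,
        dead=occ.dead + deaths,
        dead_cv=occ.dead_cv + deaths * cv_fraction,
    )
    survive = 1.0 - p_death
    incidence: dict[str, float] = {}
    for sm_id, mass in occ.masses.items():
        spec = specs[sm_id]
        index = {s: i for i, s in enumerate(spec.states)}
        scaled = mass * survive
        nxt = scaled.copy()
        exits = transitions[sm_id]
        for state, outs in exits.items():
            i = index[state]
            for to_state, p in outs:
                moved = scaled[i] * p
                nxt[i] -= moved
                nxt[index[to_state]] += moved
                incidence[to_state] = incidence.get(to_state, 0.0) + moved
        if np.any(nxt < -MASS_TOL):
            raise ModelStructureError(
                f"submodel {sm_id!r}: negative occupancy after transition"
            )
        np.clip(nxt, 0.0, None, out=nxt)
        new.masses[sm_id] = nxt
    return new, incidence


@dataclass
class SimulationResult:
    """Per-cycle traces for one arm of the cohort simulation."""

    arm: str
    states: dict[str, list[str]]  # submodel_id -> ordered states
    occupancy: dict[str, np.ndarray]  # state_id -> per-cycle end-of-cycle mass
    incidence: dict[str, np.ndarray]  # state_id -> per-cycle incident mass
    alive: np.ndarray  # end-of-cycle alive mass
    alive_start: np.ndarray  # start-of-cycle alive mass
    deaths: np.ndarray  # per-cycle death mass
    deaths_cv: np.ndarray  # per-cycle cardiovascular death mass
    path: "RiskFactorPath"
    trace: list[StateOccupancy]

    @property
    def horizon(self) -> int:
        return len(self.alive)

    @property
    def cumulative_mortality(self) -> float:
        return float(self.deaths.sum())

    @property
    def cumulative_cv_mortality(self) -> float:
        return float(self.deaths_cv.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cycle export (cycle, arm, submodel, state, occupancy, incidence)."""
        rows = []
        for sm_id, states in self.states.items():
            for state in states:
                occ = self.occupancy[state]
                inc = self.incidence[state]
                for t in range(self.horizon):
                    rows.append(
                        {
                            "cycle": t,
                            "arm": self.arm,
                            "submodel": sm_id,
                            "state": state,
                            "occupancy": occ[t],
                            "incident_probability": inc[t],
                        }
                    )
        return pd.DataFrame(rows)


def _history_fractions(
    occ: StateOccupancy,
    history_map: dict[str, list[str]],
    state_index: dict[str, tuple[str, int]],
) -> dict[str, float]:
    if occ.alive <= 0.0:
        return {name: 0.0 for name in history_map}
    out = {}
    for name, states in history_map.items():
        total = 0.0
        for state in states:
            sm_id, i = state_index[state]
            total += occ.masses[sm_id][i]
        out[name] = min(total / occ.alive, 1.0)
    return out


def run_cohort(config: "ModelConfig", arm: str) -> SimulationResult:
    """Propagate the cohort through all sub-models for one arm.

    Deterministic: no randomness anywhere in the engine.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    horizon = config.econ.horizon_years
    if horizon > 40:
        raise ValueError("horizon exceeds the engine's 40-year upper limit")
    strategy = (
        config.arm_intervention if arm == "intervention" else config.arm_comparator
    )
    path = hba1c_trajectory(
        strategy, config.hba1c_drift_per_year, config.switch_rule, horizon
    )
    equations = config.equations
    specs = {sm.submodel_id: sm for sm in config.submodels}
    state_index: dict[str, tuple[str, int]] = {}
    for sm in config.submodels:
        for i, s in enumerate(sm.states):
            state_index[s] = (sm.submodel_id, i)

    cohort = config.cohort
    base_cov = CovariateVector(
        age=cohort.age_years,
        female=cohort.prop_female,
        smoker=cohort.prop_smoker,
        duration=cohort.duration_years,
        hba1c_pct=cohort.hba1c_pct,
        sbp=cohort.sbp_mmHg,
        dbp=cohort.dbp_mmHg,
        bmi=cohort.bmi,
        tc=cohort.tc_mmol,
        ldl=cohort.ldl_mmol,
        hdl=cohort.hdl_mmol,
        tg=cohort.tg_mmol,
        heart_rate=cohort.heart_rate_bpm,
        wbc=cohort.wbc,
        egfr=cohort.egfr,
    )

    occ = StateOccupancy.initial(config.submodels)
    occupancy = {s: np.zeros(horizon) for s in state_index}
    incidence = {s: np.zeros(horizon) for s in state_index}
    alive = np.zeros(horizon)
    alive_start = np.zeros(horizon)
    deaths = np.zeros(horizon)
    deaths_cv = np.zeros(horizon)
    trace: list[StateOccupancy] = []

    mort = config.mortality
    histories_max: dict[str, float] = {k: 0.0 for k in config.history_covariates}

    for t in range(horizon):
        fractions = _history_fractions(occ, config.history_covariates, state_index)
        # once accrued, an expected history fraction never decreases
        for name, value in fractions.items():
            histories_max[name] = max(histories_max[name], value)
        cov = CovariateVector(
            age=base_cov.age + t,
            female=base_cov.female,
            smoker=base_cov.smoker,
            duration=base_cov.duration + t,
            hba1c_pct=float(path.hba1c[t]),
            sbp=float(path.sbp[t]),
            dbp=float(path.dbp[t]),
            bmi=float(path.bmi[t]),
            tc=base_cov.tc,
            ldl=base_cov.ldl,
            hdl=base_cov.hdl,
            tg=base_cov.tg,
            heart_rate=base_cov.heart_rate,
            wbc=base_cov.wbc,
            egfr=base_cov.egfr,
            **histories_max,
        )
        p_other = 0.0
        p_cv = 0.0
        if mort is not None:
            p_other = annual_event_probability(
                equations[mort.all_cause_equation], cov
            )
            if mort.cv_equation is not None:
                p_cv = annual_event_probability(equations[mort.cv_equation], cov)
        p_death = 1.0 - (1.0 - p_other) * (1.0 - p_cv)
        cv_fraction = p_cv / (p_cv + p_other) if (p_cv + p_other) > 0 else 0.0

        transitions = {
            sm_id: build_transition_probabilities(spec, cov, equations)
            for sm_id, spec in specs.items()
        }
        alive_start[t] = occ.alive
        new_occ, inc = propagate_cycle(occ, transitions, specs, p_death, cv_fraction)
        new_occ.validate(specs)
        deaths[t] = new_occ.dead - occ.dead
        deaths_cv[t] = new_occ.dead_cv - occ.dead_cv
        for state, mass in inc.items():
            incidence[state][t] = mass
        for sm_id, spec in specs.items():
            for i, state in enumerate(spec.states):
                occupancy[state][t] = new_occ.masses[sm_id][i]
        alive[t] = new_occ.alive
        trace.append(new_occ)
        occ = new_occ

    return SimulationResult(
        arm=arm,
        states={sm.submodel_id: list(sm.states) for sm in config.submodels},
        occupancy=occupancy,
        incidence=incidence,
        alive=alive,
        alive_start=alive_start,
        deaths=deaths,
        deaths_cv=deaths_cv,
        path=path,
        trace=trace,
    )


def cumulative_incidence(result: SimulationResult, state: str) -> float:
    """Cumulative incidence of ever entering ``state``, in percent."""
    if state not in result.incidence:
        raise KeyError(f"unknown state {state!r}")
    value = 100.0 * float(result.incidence[state].sum())
    return min(max(value, 0.0), 100.0)


def relative_risk(ci_intervention: float, ci_comparator: float) -> float:
    """Ratio of cumulative incidences, rounded to 2 decimals for reporting."""
    if ci_comparator == 0:
        raise ZeroDivisionError("comparator cumulative incidence is zero")
    return round(ci_intervention / ci_comparator, 2)


def percent_reduction(ci_intervention: float, ci_comparator: float) -> float:
    """Percent reduction relative to the comparator, rounded to 1 decimal."""
    if ci_comparator == 0:
        raise ZeroDivisionError("comparator cumulative incidence is zero")
    return round(100.0 * (ci_comparator - ci_intervention) / ci_comparator, 1)
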