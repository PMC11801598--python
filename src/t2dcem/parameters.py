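"""Model parameterization: types, validation, YAML I/O, bundled defaults.

The YAML configuration document is the single source of truth for every
model input (cohort profile, treatment strategies, sub-model structure,
cost and utility catalogs, economic settings).  Loading is strict: unknown
keys are rejected, every cross-reference must resolve, and the bundled
default parameter set passes validation with zero warnings.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .cohort_engine import MarkovSubModelSpec, Transition
from .risk_equations import RiskEquationSpec, load_risk_equations

__all__ = [
    "ConfigError",
    "SchemaError",
    "CrossReferenceError",
    "ValueSE",
    "CohortProfile",
    "TreatmentStrategy",
    "SwitchRule",
    "ComplicationCostEntry",
    "UtilityCatalog",
    "EconomicSettings",
    "MortalitySpec",
    "TreatmentEffectCI",
    "ModelConfig",
    "load_model_config",
    "save_model_config",
    "default_paper_config",
    "get_by_path",
    "set_by_path",
]

SCHEMA_VERSION = 1

BUILTIN_PREFIX = "builtin:"


class ConfigError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ConfigError):
    """A field is missing, unknown, or violates its invariant."""


class CrossReferenceError(ConfigError):
    """A reference to a state or equation does not resolve."""


def _require_keys(data: dict, required: set[str], optional: set[str], where: str) -> None:
    if not isinstance(data, dict):
        raise SchemaError(f"{where}: expected a mapping, got {type(data).__name__}")
    missing = required - data.keys()
    if missing:
        raise SchemaError(f"{where}: missing field(s) {sorted(missing)}")
    extra = data.keys() - required - optional
    if extra:
        raise SchemaError(f"{where}: unknown field(s) {sorted(extra)}")


def _finite(value: Any, where: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{where}: not a number: {value!r}") from None
    if not math.isfinite(v):
        raise SchemaError(f"{where}: not finite: {value!r}")
    return v


@dataclass
class ValueSE:
    """A point value with its standard error (``se`` may be None)."""

    mean: float
    se: float | None = None

    @classmethod
    def from_dict(cls, data: Any, where: str) -> "ValueSE":
        _require_keys(data, {"mean"}, {"se"}, where)
        se = data.get("se")
        return cls(
            mean=_finite(data["mean"], f"{where}.mean"),
            se=None if se is None else _finite(se, f"{where}.se"),
        )

    def to_dict(self) -> dict:
        return {"mean": self.mean, "se": self.se}


@dataclass
class CohortProfile:
    age_years: float
    duration_years: float
    prop_female: float
    prop_smoker: float
    hba1c_pct: float
    sbp_mmHg: float
    dbp_mmHg: float
    tc_mmol: float
    ldl_mmol: float
    hdl_mmol: float
    tg_mmol: float
    bmi: float
    heart_rate_bpm: float
    wbc: float
    egfr: float

    _FRACTIONS = ("prop_female", "prop_smoker")

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise SchemaError(f"cohort.{f.name}: not finite")
            if f.name in self._FRACTIONS:
                if not 0.0 <= v <= 1.0:
                    raise SchemaError(f"cohort.{f.name}: {v} outside [0, 1]")
            elif v <= 0:
                raise SchemaError(f"cohort.{f.name}: {v} must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "CohortProfile":
        names = {f.name for f in fields(cls)}
        _require_keys(data, names, set(), "cohort")
        return cls(**{k: _finite(v, f"cohort.{k}") for k, v in data.items()})

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class TreatmentStrategy:
    name: str
    hba1c_on_treatment: float
    bmi_on_treatment: float
    sbp_on_treatment: float
    dbp_on_treatment: float
    hypo_nonsevere_rate: float
    hypo_severe_rate: float
    drug_cost_daily: float
    needle_cost_daily: float
    smbg_cost_daily: float
    injections_per_day: int
    #: optional cost breakdown (e.g. GLP-1RA + basal insulin) summed at load
    drug_cost_components: list[float] | None = None

    def validate(self) -> None:
        where = f"strategy {self.name!r}"
        for attr in ("hypo_nonsevere_rate", "hypo_severe_rate"):
            if getattr(self, attr) < 0:
                raise SchemaError(f"{where}: {attr} must be >= 0")
        for attr in ("drug_cost_daily", "needle_cost_daily", "smbg_cost_daily"):
            if getattr(self, attr) < 0:
                raise SchemaError(f"{where}: {attr} must be >= 0")
        if self.injections_per_day < 0 or self.injections_per_day != int(
            self.injections_per_day
        ):
            raise SchemaError(f"{where}: injections_per_day must be a whole number >= 0")

    @property
    def total_daily_cost(self) -> float:
        return self.drug_cost_daily + self.needle_cost_daily + self.smbg_cost_daily

    def annual_cost(self, days_per_year: float) -> float:
        return self.total_daily_cost * days_per_year

    @classmethod
    def from_dict(cls, data: dict, where: str) -> "TreatmentStrategy":
        names = {f.name for f in fields(cls)} - {"drug_cost_components"}
        _require_keys(data, names, set(), where)
        drug = data["drug_cost_daily"]
        components: list[float] | None = None
        if isinstance(drug, list):
            components = [_finite(v, f"{where}.drug_cost_daily[]") for v in drug]
            drug_total = float(sum(components))
        else:
            drug_total = _finite(drug, f"{where}.drug_cost_daily")
        return cls(
            name=str(data["name"]),
            hba1c_on_treatment=_finite(data["hba1c_on_treatment"], where),
            bmi_on_treatment=_finite(data["bmi_on_treatment"], where),
            sbp_on_treatment=_finite(data["sbp_on_treatment"], where),
            dbp_on_treatment=_finite(data["dbp_on_treatment"], where),
            hypo_nonsevere_rate=_finite(data["hypo_nonsevere_rate"], where),
            hypo_severe_rate=_finite(data["hypo_severe_rate"], where),
            drug_cost_daily=drug_total,
            needle_cost_daily=_finite(data["needle_cost_daily"], where),
            smbg_cost_daily=_finite(data["smbg_cost_daily"], where),
            injections_per_day=int(data["injections_per_day"]),
            drug_cost_components=components,
        )

    def to_dict(self) -> dict:
        drug: Any = (
            list(self.drug_cost_components)
            if self.drug_cost_components is not None
            else self.drug_cost_daily
        )
        return {
            "name": self.name,
            "hba1c_on_treatment": self.hba1c_on_treatment,
            "bmi_on_treatment": self.bmi_on_treatment,
            "sbp_on_treatment": self.sbp_on_treatment,
            "dbp_on_treatment": self.dbp_on_treatment,
            "hypo_nonsevere_rate": self.hypo_nonsevere_rate,
            "hypo_severe_rate": self.hypo_severe_rate,
            "drug_cost_daily": drug,
            "needle_cost_daily": self.needle_cost_daily,
            "smbg_cost_daily": self.smbg_cost_daily,
            "injections_per_day": self.injections_per_day,
        }


@dataclass
class SwitchRule:
    hba1c_threshold_pct: float
    post_switch_strategy: TreatmentStrategy

    def validate(self) -> None:
        if self.hba1c_threshold_pct <= 0:
            raise SchemaError("switch_rule.hba1c_threshold_pct must be > 0")
        self.post_switch_strategy.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "SwitchRule":
        _require_keys(
            data, {"hba1c_threshold_pct", "post_switch_strategy"}, set(), "switch_rule"
        )
        return cls(
            hba1c_threshold_pct=_finite(
                data["hba1c_threshold_pct"], "switch_rule.hba1c_threshold_pct"
            ),
            post_switch_strategy=TreatmentStrategy.from_dict(
                data["post_switch_strategy"], "switch_rule.post_switch_strategy"
            ),
        )

    def to_dict(self) -> dict:
        return {
            "hba1c_threshold_pct": self.hba1c_threshold_pct,
            "post_switch_strategy": self.post_switch_strategy.to_dict(),
        }


@dataclass
class ComplicationCostEntry:
    """Event cost (year of the event) and annual state cost for one state."""

    state_id: str
    event_cost: float
    state_cost: float
    event_cost_se: float | None = None
    state_cost_se: float | None = None

    def validate(self) -> None:
        if self.event_cost < 0 or self.state_cost < 0:
            raise SchemaError(f"costs.{self.state_id}: costs must be >= 0")

    @classmethod
    def from_dict(cls, state_id: str, data: dict) -> "ComplicationCostEntry":
        where = f"costs.{state_id}"
        _require_keys(
            data,
            {"event_cost", "state_cost"},
            {"event_cost_se", "state_cost_se"},
            where,
        )
        return cls(
            state_id=state_id,
            event_cost=_finite(data["event_cost"], f"{where}.event_cost"),
            state_cost=_finite(data["state_cost"], f"{where}.state_cost"),
            event_cost_se=(
                None
                if data.get("event_cost_se") is None
                else _finite(data["event_cost_se"], where)
            ),
            state_cost_se=(
                None
                if data.get("state_cost_se") is None
                else _finite(data["state_cost_se"], where)
            ),
        )

    def to_dict(self) -> dict:
        out: dict = {"event_cost": self.event_cost, "state_cost": self.state_cost}
        if self.event_cost_se is not None:
            out["event_cost_se"] = self.event_cost_se
        if self.state_cost_se is not None:
            out["state_cost_se"] = self.state_cost_se
        return out


_DEMOGRAPHIC_KEYS = ("age_per_10_years", "female", "duration_per_10_years", "bmi_per_unit")


@dataclass
class UtilityCatalog:
    """Baseline utility and additive decrements (all decrements <= 0)."""

    baseline: ValueSE
    bmi_anchor: float
    age_per_10_years: ValueSE
    female: ValueSE
    duration_per_10_years: ValueSE
    bmi_per_unit: ValueSE
    state_decrements: dict[str, ValueSE]
    hypo_nonsevere: ValueSE
    hypo_severe: ValueSE
    injections: dict[int, ValueSE]

    @property
    def baseline_utility(self) -> float:
        return self.baseline.mean

    def state_decrement(self, state_id: str) -> float:
        return self.state_decrements[state_id].mean

    def injection_disutility(self, injections_per_day: int) -> float:
        n = int(injections_per_day)
        if n == 0:
            return 0.0
        if n not in self.injections:
            raise CrossReferenceError(
                f"utilities: no disutility entry for {n} injections/day"
            )
        return self.injections[n].mean

    def validate(self) -> None:
        if not 0.0 < self.baseline.mean <= 1.0:
            raise SchemaError("utilities.baseline.mean must be in (0, 1]")
        decs = [
            ("demographic." + k, getattr(self, k))
            for k in _DEMOGRAPHIC_KEYS
        ]
        decs += [(f"states.{k}", v) for k, v in self.state_decrements.items()]
        decs += [
            ("events.hypo_nonsevere", self.hypo_nonsevere),
            ("events.hypo_severe", self.hypo_severe),
        ]
        decs += [(f"injections_per_day.{k}", v) for k, v in self.injections.items()]
        for where, v in decs:
            if v.mean > 0:
                raise SchemaError(f"utilities.{where}: decrement must be <= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "UtilityCatalog":
        _require_keys(
            data,
            {"baseline", "bmi_anchor", "demographic", "states", "events",
             "injections_per_day"},
            set(),
            "utilities",
        )
        demo = data["demographic"]
        _require_keys(demo, set(_DEMOGRAPHIC_KEYS), set(), "utilities.demographic")
        events = data["events"]
        _require_keys(
            events, {"hypo_nonsevere", "hypo_severe"}, set(), "utilities.events"
        )
        states = {
            str(k): ValueSE.from_dict(v, f"utilities.states.{k}")
            for k, v in data["states"].items()
        }
        injections = {}
        for k, v in data["injections_per_day"].items():
            try:
                n = int(k)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"utilities.injections_per_day: bad key {k!r}"
                ) from None
            injections[n] = ValueSE.from_dict(v, f"utilities.injections_per_day.{k}")
        return cls(
            baseline=ValueSE.from_dict(data["baseline"], "utilities.baseline"),
            bmi_anchor=_finite(data["bmi_anchor"], "utilities.bmi_anchor"),
            age_per_10_years=ValueSE.from_dict(
                demo["age_per_10_years"], "utilities.demographic.age_per_10_years"
            ),
            female=ValueSE.from_dict(demo["female"], "utilities.demographic.female"),
            duration_per_10_years=ValueSE.from_dict(
                demo["duration_per_10_years"],
                "utilities.demographic.duration_per_10_years",
            ),
            bmi_per_unit=ValueSE.from_dict(
                demo["bmi_per_unit"], "utilities.demographic.bmi_per_unit"
            ),
            state_decrements=states,
            hypo_nonsevere=ValueSE.from_dict(
                events["hypo_nonsevere"], "utilities.events.hypo_nonsevere"
            ),
            hypo_severe=ValueSE.from_dict(
                events["hypo_severe"], "utilities.events.hypo_severe"
            ),
            injections=injections,
        )

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "bmi_anchor": self.bmi_anchor,
            "demographic": {
                k: getattr(self, k).to_dict() for k in _DEMOGRAPHIC_KEYS
            },
            "states": {k: v.to_dict() for k, v in self.state_decrements.items()},
            "events": {
                "hypo_nonsevere": self.hypo_nonsevere.to_dict(),
                "hypo_severe": self.hypo_severe.to_dict(),
            },
            "injections_per_day": {k: v.to_dict() for k, v in self.injections.items()},
        }


@dataclass
class EconomicSettings:
    horizon_years: int
    discount_rate_cost: float
    discount_rate_qaly: float
    wtp_threshold: float
    days_per_year: float = 365.25
    discount_from_cycle_one: bool = False
    half_cycle_correction: bool = False

    def validate(self) -> None:
        if not 1 <= self.horizon_years <= 40:
            raise SchemaError(
                "econ.horizon_years must be within [1, 40] (engine's 40-year limit)"
            )
        for attr in ("discount_rate_cost", "discount_rate_qaly"):
            if not 0.0 <= getattr(self, attr) <= 0.2:
                raise SchemaError(f"econ.{attr} must be within [0, 0.2]")
        if self.wtp_threshold <= 0:
            raise SchemaError("econ.wtp_threshold must be > 0")
        if self.days_per_year <= 0:
            raise SchemaError("econ.days_per_year must be > 0")

    @classmethod
    def from_dict(cls, data: dict) -> "EconomicSettings":
        _require_keys(
            data,
            {"horizon_years", "discount_rate_cost", "discount_rate_qaly",
             "wtp_threshold"},
            {"days_per_year", "discount_from_cycle_one", "half_cycle_correction"},
            "econ",
        )
        return cls(
            horizon_years=int(data["horizon_years"]),
            discount_rate_cost=_finite(data["discount_rate_cost"], "econ"),
            discount_rate_qaly=_finite(data["discount_rate_qaly"], "econ"),
            wtp_threshold=_finite(data["wtp_threshold"], "econ"),
            days_per_year=_finite(data.get("days_per_year", 365.25), "econ"),
            discount_from_cycle_one=bool(data.get("discount_from_cycle_one", False)),
            half_cycle_correction=bool(data.get("half_cycle_correction", False)),
        )

    def to_dict(self) -> dict:
        return {
            "horizon_years": self.horizon_years,
            "discount_rate_cost": self.discount_rate_cost,
            "discount_rate_qaly": self.discount_rate_qaly,
            "wtp_threshold": self.wtp_threshold,
            "days_per_year": self.days_per_year,
            "discount_from_cycle_one": self.discount_from_cycle_one,
            "half_cycle_correction": self.half_cycle_correction,
        }


@dataclass
class MortalitySpec:
    all_cause_equation: str
    cv_equation: str | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "MortalitySpec":
        _require_keys(data, {"all_cause_equation"}, {"cv_equation"}, "mortality")
        return cls(
            all_cause_equation=str(data["all_cause_equation"]),
            cv_equation=(
                None if data.get("cv_equation") is None else str(data["cv_equation"])
            ),
        )

    def to_dict(self) -> dict:
        return {
            "all_cause_equation": self.all_cause_equation,
            "cv_equation": self.cv_equation,
        }


@dataclass
class TreatmentEffectCI:
    """A between-arm effect with its 95% CI (for PSA normal draws)."""

    mean: float
    low: float | None = None
    high: float | None = None

    @classmethod
    def from_dict(cls, data: dict, where: str) -> "TreatmentEffectCI":
        _require_keys(data, {"mean"}, {"low", "high"}, where)
        low = data.get("low")
        high = data.get("high")
        return cls(
            mean=_finite(data["mean"], where),
            low=None if low is None else _finite(low, where),
            high=None if high is None else _finite(high, where),
        )

    def to_dict(self) -> dict:
        return {"mean": self.mean, "low": self.low, "high": self.high}


@dataclass
class ModelConfig:
    cohort: CohortProfile
    arm_intervention: TreatmentStrategy
    arm_comparator: TreatmentStrategy
    switch_rule: SwitchRule
    submodels: list[MarkovSubModelSpec]
    costs: dict[str, ComplicationCostEntry]
    background_cost: ValueSE
    hypo_costs: dict[str, ValueSE]  # keys: nonsevere, severe (event costs)
    utilities: UtilityCatalog
    econ: EconomicSettings
    hba1c_drift_per_year: float
    mortality: MortalitySpec | None
    history_covariates: dict[str, list[str]]
    cost_categories: dict[str, list[str]]
    risk_coefficients: str
    treatment_effects: dict[str, TreatmentEffectCI] = field(default_factory=dict)
    _equations: dict[str, RiskEquationSpec] | None = field(
        default=None, repr=False, compare=False
    )
    _base_dir: Path | None = field(default=None, repr=False, compare=False)

    # -- derived ----------------------------------------------------------

    @property
    def equations(self) -> dict[str, RiskEquationSpec]:
        if self._equations is None:
            self._equations = load_risk_equations(self.resolve_coefficients_path())
        return self._equations

    def resolve_coefficients_path(self) -> Path:
        ref = self.risk_coefficients
        if ref.startswith(BUILTIN_PREFIX):
            name = ref[len(BUILTIN_PREFIX):]
            return Path(str(importlib.resources.files("t2dcem") / "data" / name))
        p = Path(ref)
        if not p.is_absolute() and self._base_dir is not None:
            p = self._base_dir / p
        return p

    def all_states(self) -> dict[str, str]:
        """state_id -> submodel_id for every state in every sub-model."""
        out: dict[str, str] = {}
        for sm in self.submodels:
            for s in sm.states:
                out[s] = sm.submodel_id
        return out

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        self.cohort.validate()
        self.arm_intervention.validate()
        self.arm_comparator.validate()
        self.switch_rule.validate()
        for entry in self.costs.values():
            entry.validate()
        if self.background_cost.mean < 0:
            raise SchemaError("background_cost.mean must be >= 0")
        for key in ("nonsevere", "severe"):
            if key not in self.hypo_costs:
                raise SchemaError(f"hypo_costs: missing {key!r}")
            if self.hypo_costs[key].mean < 0:
                raise SchemaError(f"hypo_costs.{key} must be >= 0")
        self.utilities.validate()
        self.econ.validate()
        if self.hba1c_drift_per_year < 0:
            raise SchemaError("hba1c_drift_per_year must be >= 0")
        if self.cohort.age_years + self.econ.horizon_years > 120:
            raise SchemaError("cohort age plus horizon exceeds 120 years")

        # state uniqueness across sub-models
        seen: dict[str, str] = {}
        for sm in self.submodels:
            for s in sm.states:
                if s in seen:
                    raise CrossReferenceError(
                        f"state {s!r} appears in sub-models "
                        f"{seen[s]!r} and {sm.submodel_id!r}"
                    )
                seen[s] = sm.submodel_id

        states = set(seen)
        for state_id in self.costs:
            if state_id not in states:
                raise CrossReferenceError(f"costs: unknown state {state_id!r}")
        for state_id in self.utilities.state_decrements:
            if state_id not in states:
                raise CrossReferenceError(f"utilities.states: unknown state {state_id!r}")
        # every costed state must carry an explicit utility decrement (zero allowed)
        for state_id in self.costs:
            if state_id not in self.utilities.state_decrements:
                raise CrossReferenceError(
                    f"state {state_id!r} has a cost entry but no utility decrement "
                    "(add an explicit zero)"
                )
        for name, hist_states in self.history_covariates.items():
            if not name.startswith("prior_"):
                raise SchemaError(f"history_covariates: bad indicator name {name!r}")
            for s in hist_states:
                if s not in states:
                    raise CrossReferenceError(
                        f"history_covariates.{name}: unknown state {s!r}"
                    )
        claimed: set[str] = set()
        for category, cat_states in self.cost_categories.items():
            for s in cat_states:
                if s not in self.costs:
                    raise CrossReferenceError(
                        f"cost_categories.{category}: state {s!r} has no cost entry"
                    )
                if s in claimed:
                    raise CrossReferenceError(
                        f"cost_categories: state {s!r} assigned to multiple categories"
                    )
                claimed.add(s)
        unclaimed = set(self.costs) - claimed
        if unclaimed:
            raise CrossReferenceError(
                f"cost_categories: costed state(s) not in any category: "
                f"{sorted(unclaimed)}"
            )

        equations = self.equations
        for sm in self.submodels:
            for tr in sm.transitions:
                if tr.equation_id not in equations:
                    raise CrossReferenceError(
                        f"submodel {sm.submodel_id!r}: unknown equation "
                        f"{tr.equation_id!r}"
                    )
        if self.mortality is not None:
            if self.mortality.all_cause_equation not in equations:
                raise CrossReferenceError(
                    f"mortality: unknown equation {self.mortality.all_cause_equation!r}"
                )
            if (
                self.mortality.cv_equation is not None
                and self.mortality.cv_equation not in equations
            ):
                raise CrossReferenceError(
                    f"mortality: unknown equation {self.mortality.cv_equation!r}"
                )

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict, base_dir: Path | None = None) -> "ModelConfig":
        required = {
            "schema_version", "cohort", "arm_intervention", "arm_comparator",
            "switch_rule", "submodels", "costs", "background_cost", "hypo_costs",
            "utilities", "econ", "hba1c_drift_per_year", "history_covariates",
            "cost_categories", "risk_coefficients",
        }
        optional = {"mortality", "treatment_effects"}
        _require_keys(data, required, optional, "config")
        if data["schema_version"] != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported schema_version {data['schema_version']!r} "
                f"(expected {SCHEMA_VERSION})"
            )
        submodels = []
        for i, sm in enumerate(data["submodels"]):
            _require_keys(sm, {"id", "states", "transitions"}, set(), f"submodels[{i}]")
            transitions = []
            for tr in sm["transitions"]:
                if not (isinstance(tr, list) and len(tr) == 3):
                    raise SchemaError(
                        f"submodels[{i}].transitions: expected [from, to, equation], "
                        f"got {tr!r}"
                    )
                transitions.append(Transition(str(tr[0]), str(tr[1]), str(tr[2])))
            submodels.append(
                MarkovSubModelSpec(
                    submodel_id=str(sm["id"]),
                    states=[str(s) for s in sm["states"]],
                    transitions=transitions,
                )
            )
        costs = {
            str(k): ComplicationCostEntry.from_dict(str(k), v)
            for k, v in data["costs"].items()
        }
        hypo_raw = data["hypo_costs"]
        _require_keys(hypo_raw, {"nonsevere", "severe"}, set(), "hypo_costs")
        hypo_costs = {
            k: ValueSE.from_dict(v, f"hypo_costs.{k}") for k, v in hypo_raw.items()
        }
        effects = {
            str(k): TreatmentEffectCI.from_dict(v, f"treatment_effects.{k}")
            for k, v in (data.get("treatment_effects") or {}).items()
        }
        config = cls(
            cohort=CohortProfile.from_dict(data["cohort"]),
            arm_intervention=TreatmentStrategy.from_dict(
                data["arm_intervention"], "arm_intervention"
            ),
            arm_comparator=TreatmentStrategy.from_dict(
                data["arm_comparator"], "arm_comparator"
            ),
            switch_rule=SwitchRule.from_dict(data["switch_rule"]),
            submodels=submodels,
            costs=costs,
            background_cost=ValueSE.from_dict(data["background_cost"], "background_cost"),
            hypo_costs=hypo_costs,
            utilities=UtilityCatalog.from_dict(data["utilities"]),
            econ=EconomicSettings.from_dict(data["econ"]),
            hba1c_drift_per_year=_finite(
                data["hba1c_drift_per_year"], "hba1c_drift_per_year"
            ),
            mortality=(
                None
                if data.get("mortality") is None
                else MortalitySpec.from_dict(data["mortality"])
            ),
            history_covariates={
                str(k): [str(s) for s in v]
                for k, v in data["history_covariates"].items()
            },
            cost_categories={
                str(k): [str(s) for s in v]
                for k, v in data["cost_categories"].items()
            },
            risk_coefficients=str(data["risk_coefficients"]),
            treatment_effects=effects,
            _base_dir=base_dir,
        )
        return config

    def to_dict(self) -> dict:
        out: dict = {
            "schema_version": SCHEMA_VERSION,
            "cohort": self.cohort.to_dict(),
            "arm_intervention": self.arm_intervention.to_dict(),
            "arm_comparator": self.arm_comparator.to_dict(),
            "switch_rule": self.switch_rule.to_dict(),
            "hba1c_drift_per_year": self.hba1c_drift_per_year,
            "econ": self.econ.to_dict(),
            "background_cost": self.background_cost.to_dict(),
            "hypo_costs": {k: v.to_dict() for k, v in self.hypo_costs.items()},
            "costs": {k: v.to_dict() for k, v in self.costs.items()},
            "utilities": self.utilities.to_dict(),
            "submodels": [
                {
                    "id": sm.submodel_id,
                    "states": list(sm.states),
                    "transitions": [
                        [tr.from_state, tr.to_state, tr.equation_id]
                        for tr in sm.transitions
                    ],
                }
                for sm in self.submodels
            ],
            "history_covariates": {
                k: list(v) for k, v in self.history_covariates.items()
            },
            "cost_categories": {k: list(v) for k, v in self.cost_categories.items()},
            "risk_coefficients": self.risk_coefficients,
        }
        if self.mortality is not None:
            out["mortality"] = self.mortality.to_dict()
        if self.treatment_effects:
            out["treatment_effects"] = {
                k: v.to_dict() for k, v in self.treatment_effects.items()
            }
        return out


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and fully validate a YAML model configuration."""
    path = Path(path)
    with path.open() as handle:
        data = yaml.safe_load(handle)
    config = ModelConfig.from_dict(data, base_dir=path.parent)
    config.validate()
    return config


def save_model_config(config: ModelConfig, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as handle:
        yaml.safe_dump(config.to_dict(), handle, sort_keys=False)


def default_paper_config() -> ModelConfig:
    """The bundled default parameterization (30-year horizon, 5% discounting)."""
    resource = importlib.resources.files("t2dcem") / "data" / "default_config.yaml"
    return load_model_config(str(resource))


# ---------------------------------------------------------------------------
# dotted-path access (used by sensitivity analyses)
# ---------------------------------------------------------------------------


# document-schema names that differ from attribute names
_PATH_ALIASES = {"states": "state_decrements", "injections_per_day": "injections"}


def _walk(config: ModelConfig, path: str) -> tuple[Any, str | int]:
    parts = path.split(".")
    node: Any = config
    for part in parts[:-1]:
        if isinstance(node, dict):
            key: str | int = part
            if part not in node:
                try:
                    key = int(part)
                except ValueError:
                    pass
            node = node[key]
        else:
            if isinstance(node, UtilityCatalog):
                part = _PATH_ALIASES.get(part, part)
            node = getattr(node, part)
    leaf = parts[-1]
    return node, leaf


def get_by_path(config: ModelConfig, path: str) -> float:
    node, leaf = _walk(config, path)
    if isinstance(node, dict):
        key: str | int = leaf
        if leaf not in node:
            key = int(leaf)
        return node[key]
    return getattr(node, leaf)


def set_by_path(config: ModelConfig, path: str, value: float) -> None:
    node, leaf = _walk(config, path)
    if isinstance(node, dict):
        key: str | int = leaf
        if leaf not in node:
            key = int(leaf)
        node[key] = value
    else:
        setattr(node, leaf, value)
        # a direct write to a summed drug cost invalidates its breakdown
        if isinstance(node, TreatmentStrategy) and leaf == "drug_cost_daily":
            node.drug_cost_components = None
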