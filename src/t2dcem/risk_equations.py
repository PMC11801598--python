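"""Per-cycle event probabilities and risk-factor trajectories.

Event probabilities are produced by small parametric equations (constant
rate, proportional-hazards exponential, proportional-hazards Weibull on
diabetes duration, logistic) evaluated on a covariate vector.  Coefficient
sets live in a columnar text file so every number is inspectable and can be
overridden from the model configuration.

Risk factors follow a deterministic trajectory: on-treatment values with a
linear HbA1c drift until the glycaemic threshold is crossed, after which
both arms share the post-switch regimen's constant values.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import SwitchRule, TreatmentStrategy

__all__ = [
    "CovariateVector",
    "RiskEquationSpec",
    "RiskFactorPath",
    "EvaluationError",
    "EquationFileError",
    "annual_event_probability",
    "hba1c_trajectory",
    "update_covariates",
    "load_risk_equations",
    "save_risk_equations",
]

#: functional forms understood by :func:`annual_event_probability`
FORMS = ("constant_rate", "constant_prob", "ph_exponential", "ph_weibull", "logistic")


class EvaluationError(ValueError):
    """An equation referenced a covariate that is missing or invalid."""


class EquationFileError(ValueError):
    """A coefficient file failed structural validation."""


@dataclass(frozen=True)
class CovariateVector:
    """Start-of-cycle covariates for one simulated cohort.

    History indicators are expected fractions of the alive cohort (a cohort
    model carries probability mass, not individuals), and are monotone
    non-decreasing over cycles.
    """

    age: float
    female: float
    smoker: float
    duration: float
    hba1c_pct: float
    sbp: float
    dbp: float
    bmi: float
    tc: float
    ldl: float
    hdl: float
    tg: float
    heart_rate: float
    wbc: float
    egfr: float
    prior_mi: float = 0.0
    prior_stroke: float = 0.0
    prior_ihd: float = 0.0
    prior_hf: float = 0.0
    prior_amputation: float = 0.0
    prior_esrd: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


COVARIATE_NAMES = tuple(f.name for f in fields(CovariateVector))


@dataclass(frozen=True)
class RiskEquationSpec:
    """One annual-probability equation.

    ``coefficients`` maps covariate name -> (coefficient, centering
    constant).  For ``constant_rate`` the intercept is the annual hazard
    rate; for ``constant_prob`` it is the probability itself.
    """

    equation_id: str
    form: str
    intercept: float
    shape: float | None = None
    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise EquationFileError(
                f"equation {self.equation_id!r}: unknown form {self.form!r}"
            )
        if self.form == "ph_weibull" and (self.shape is None or self.shape <= 0):
            raise EquationFileError(
                f"equation {self.equation_id!r}: ph_weibull requires a positive shape"
            )
        if self.form == "constant_rate" and self.intercept < 0:
            raise EquationFileError(
                f"equation {self.equation_id!r}: constant_rate requires rate >= 0"
            )
        if self.form == "constant_prob" and not 0.0 <= self.intercept <= 1.0:
            raise EquationFileError(
                f"equation {self.equation_id!r}: constant_prob requires p in [0,1]"
            )
        for cov in self.coefficients:
            if cov not in COVARIATE_NAMES:
                raise EquationFileError(
                    f"equation {self.equation_id!r}: unknown covariate {cov!r}"
                )


def _linear_predictor(eq: RiskEquationSpec, cov: CovariateVector) -> float:
    lp = eq.intercept
    values = cov.as_dict()
    for name, (coef, center) in eq.coefficients.items():
        value = values.get(name)
        if value is None or not math.isfinite(value):
            raise EvaluationError(
                f"equation {eq.equation_id!r}: covariate {name!r} missing or non-finite"
            )
        lp += coef * (value - center)
    return lp


def annual_event_probability(eq: RiskEquationSpec, cov: CovariateVector) -> float:
    """Annual transition probability for one equation at given covariates.

    Proportional-hazards forms return ``1 - exp(-dH)`` where ``dH`` is the
    cumulative-hazard increment over the coming cycle; the Weibull form uses
    diabetes duration as its time scale.
    """
    if eq.form == "constant_rate":
        return 1.0 - math.exp(-eq.intercept)
    if eq.form == "constant_prob":
        return eq.intercept
    lp = _linear_predictor(eq, cov)
    if eq.form == "ph_exponential":
        return 1.0 - math.exp(-math.exp(lp))
    if eq.form == "ph_weibull":
        d0 = max(cov.duration, 0.0)
        d_h = math.exp(lp) * ((d0 + 1.0) ** eq.shape - d0**eq.shape)
        return 1.0 - math.exp(-d_h)
    if eq.form == "logistic":
        return 1.0 / (1.0 + math.exp(-lp))
    raise AssertionError(f"unreachable form {eq.form!r}")  # pragma: no cover


@dataclass
class RiskFactorPath:
    """Per-cycle modifiable risk factors and treatment attributes for one arm."""

    hba1c: np.ndarray
    bmi: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    hypo_nonsevere_rate: np.ndarray
    hypo_severe_rate: np.ndarray
    injections_per_day: np.ndarray
    daily_treatment_cost: np.ndarray
    labels: list[str]
    switch_cycle: int | None

    @property
    def horizon(self) -> int:
        return len(self.hba1c)


def hba1c_trajectory(
    strategy: "TreatmentStrategy",
    drift: float,
    rule: "SwitchRule",
    horizon: int,
) -> RiskFactorPath:
    """Build the risk-factor path for one arm.

    HbA1c starts at the strategy's on-treatment value and rises by ``drift``
    percentage points per cycle.  The first cycle whose HbA1c exceeds the
    threshold becomes the switch cycle; from then on every field takes the
    (constant) post-switch regimen values, so both arms' post-switch
    segments are identical.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if drift < 0:
        raise ValueError("drift must be >= 0")
    post = rule.post_switch_strategy
    n = horizon
    hba1c = np.empty(n)
    bmi = np.empty(n)
    sbp = np.empty(n)
    dbp = np.empty(n)
    ns = np.empty(n)
    sev = np.empty(n)
    inj = np.empty(n)
    cost = np.empty(n)
    labels: list[str] = []
    switch_cycle: int | None = None
    for t in range(n):
        candidate = strategy.hba1c_on_treatment + drift * t
        if switch_cycle is None and candidate > rule.hba1c_threshold_pct:
            switch_cycle = t
        on = strategy if switch_cycle is None else post
        hba1c[t] = candidate if switch_cycle is None else post.hba1c_on_treatment
        bmi[t] = on.bmi_on_treatment
        sbp[t] = on.sbp_on_treatment
        dbp[t] = on.dbp_on_treatment
        ns[t] = on.hypo_nonsevere_rate
        sev[t] = on.hypo_severe_rate
        inj[t] = on.injections_per_day
        cost[t] = on.drug_cost_daily + on.needle_cost_daily + on.smbg_cost_daily
        labels.append(on.name)
    return RiskFactorPath(
        hba1c=hba1c,
        bmi=bmi,
        sbp=sbp,
        dbp=dbp,
        hypo_nonsevere_rate=ns,
        hypo_severe_rate=sev,
        injections_per_day=inj,
        daily_treatment_cost=cost,
        labels=labels,
        switch_cycle=switch_cycle,
    )


def update_covariates(
    cov: CovariateVector,
    path: RiskFactorPath,
    cycle: int,
    histories: dict[str, float] | None = None,
) -> CovariateVector:
    """Advance covariates by one cycle.

    Age and duration increase by exactly one year; modifiable factors are
    replaced by the path values at ``cycle``; history fractions are merged
    monotonically (they can only grow).
    """
    if cycle >= path.horizon:
        raise ValueError(f"cycle {cycle} outside path horizon {path.horizon}")
    updates: dict[str, float] = {
        "age": cov.age + 1.0,
        "duration": cov.duration + 1.0,
        "hba1c_pct": float(path.hba1c[cycle]),
        "bmi": float(path.bmi[cycle]),
        "sbp": float(path.sbp[cycle]),
        "dbp": float(path.dbp[cycle]),
    }
    if histories:
        for name, value in histories.items():
            if not name.startswith("prior_"):
                raise ValueError(f"not a history indicator: {name!r}")
            updates[name] = max(getattr(cov, name), float(value))
    return replace(cov, **updates)


# ---------------------------------------------------------------------------
# coefficient file I/O
# ---------------------------------------------------------------------------

_SPECIAL = ("__form__", "__intercept__", "__shape__")
_HEADER = ["equation_id", "term", "value", "center"]


def load_risk_equations(path: str | Path) -> dict[str, RiskEquationSpec]:
    """Read a coefficient file (CSV: equation_id, term, value, center).

    Special terms ``__form__``, ``__intercept__`` and ``__shape__`` define
    the functional form; every other term is a covariate coefficient with an
    optional centering constant.
    """
    path = Path(path)
    rows: dict[str, dict] = {}
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != _HEADER:
            raise EquationFileError(
                f"{path}: expected header {_HEADER}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            eq_id = row["equation_id"].strip()
            term = row["term"].strip()
            if not eq_id or not term:
                raise EquationFileError(f"{path}:{lineno}: empty equation_id or term")
            entry = rows.setdefault(
                eq_id, {"form": None, "intercept": None, "shape": None, "coefs": {}}
            )
            if term == "__form__":
                entry["form"] = row["value"].strip()
            elif term == "__intercept__":
                entry["intercept"] = float(row["value"])
            elif term == "__shape__":
                entry["shape"] = float(row["value"])
            else:
                center = row["center"].strip()
                entry["coefs"][term] = (
                    float(row["value"]),
                    float(center) if center else 0.0,
                )
    equations: dict[str, RiskEquationSpec] = {}
    for eq_id, entry in rows.items():
        if entry["form"] is None:
            raise EquationFileError(f"{path}: equation {eq_id!r} has no __form__ row")
        if entry["intercept"] is None:
            raise EquationFileError(
                f"{path}: equation {eq_id!r} has no __intercept__ row"
            )
        equations[eq_id] = RiskEquationSpec(
            equation_id=eq_id,
            form=entry["form"],
            intercept=entry["intercept"],
            shape=entry["shape"],
            coefficients=entry["coefs"],
        )
    return equations


def save_risk_equations(
    equations: dict[str, RiskEquationSpec], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_HEADER)
        for eq_id in sorted(equations):
            eq = equations[eq_id]
            writer.writerow([eq_id, "__form__", eq.form, ""])
            writer.writerow([eq_id, "__intercept__", repr(eq.intercept), ""])
            if eq.shape is not None:
                writer.writerow([eq_id, "__shape__", repr(eq.shape), ""])
            for cov in sorted(eq.coefficients):
                coef, center = eq.coefficients[cov]
                writer.writerow([eq_id, cov, repr(coef), repr(center)])
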