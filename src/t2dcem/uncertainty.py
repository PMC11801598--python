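"""One-way deterministic sensitivity analysis and probabilistic sensitivity
analysis (second-order Monte Carlo) with cost-effectiveness acceptability.

Distribution conventions: beta for utilities and probabilities (decrement
magnitudes are sampled on (0,1) and re-negated), gamma for costs (default
standard error 10% of the mean when none is given), normal for between-arm
treatment effects parameterized by their 95% confidence intervals.
Parameters are drawn independently, in sorted-path order, from one seeded
generator per run, so results are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort_engine import run_cohort
from .economics import CEResult, build_ledger, classify_increments, summarize_ce
from .parameters import ConfigError, ModelConfig, get_by_path, set_by_path

__all__ = [
    "ParamDistribution",
    "TornadoEntry",
    "PsaDraws",
    "InfeasibleDistributionError",
    "beta_from_moments",
    "gamma_from_moments",
    "normal_sd_from_ci",
    "run_ce_analysis",
    "default_distributions",
    "default_owsa_ranges",
    "one_way_sensitivity",
    "run_psa",
    "ceac",
]

logger = logging.getLogger(__name__)

DEFAULT_COST_SE_FRACTION = 0.10

EFFECT_PREFIX = "effect:"


class InfeasibleDistributionError(ValueError):
    """Requested moments cannot be matched by the requested family."""


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shapes for a given mean and standard error."""
    if not 0.0 < mean < 1.0:
        raise InfeasibleDistributionError(f"beta mean {mean} outside (0, 1)")
    var = se * se
    if var <= 0.0 or var >= mean * (1.0 - mean):
        raise InfeasibleDistributionError(
            f"beta requires 0 < se^2 < mean(1-mean); got se^2={var}, "
            f"bound={mean * (1.0 - mean)}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale) for a given mean and SE."""
    if mean <= 0 or se <= 0:
        raise InfeasibleDistributionError(
            f"gamma requires mean > 0 and se > 0; got mean={mean}, se={se}"
        )
    return mean * mean / (se * se), se * se / mean


def normal_sd_from_ci(low: float, high: float) -> float:
    """Standard deviation implied by a 95% confidence interval."""
    if high < low:
        raise ValueError("upper CI bound below lower bound")
    return (high - low) / 3.92


@dataclass(frozen=True)
class ParamDistribution:
    """Second-order uncertainty for one scalar parameter.

    ``path`` is a dotted path into the configuration, or an ``effect:``
    pseudo-path applied to the intervention arm relative to the comparator.
    ``sign=-1`` samples a magnitude on (0,1) and negates it (utility
    decrements).
    """

    path: str
    family: str  # beta | gamma | normal | fixed
    mean: float
    se: float = 0.0
    sign: int = 1

    def validate(self) -> None:
        if self.family not in ("beta", "gamma", "normal", "fixed"):
            raise InfeasibleDistributionError(
                f"{self.path}: unknown family {self.family!r}"
            )
        if self.family == "beta":
            beta_from_moments(abs(self.mean), self.se)
        elif self.family == "gamma":
            gamma_from_moments(abs(self.mean), self.se)
        elif self.family == "normal" and self.se < 0:
            raise InfeasibleDistributionError(f"{self.path}: negative sd")

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.mean
        if self.family == "normal":
            return float(rng.normal(self.mean, self.se))
        if self.family == "beta":
            a, b = beta_from_moments(abs(self.mean), self.se)
            return self.sign * float(rng.beta(a, b))
        a, scale = gamma_from_moments(abs(self.mean), self.se)
        return self.sign * float(rng.gamma(a, scale))


def run_ce_analysis(config: ModelConfig) -> CEResult:
    """Run both arms plus economics and summarize increments."""
    int_ledger = build_ledger(run_cohort(config, "intervention"), config)
    comp_ledger = build_ledger(run_cohort(config, "comparator"), config)
    return summarize_ce(int_ledger, comp_ledger, config.econ)


# ---------------------------------------------------------------------------
# default parameter sets
# ---------------------------------------------------------------------------


def _cost_se(mean: float, se: float | None) -> float:
    return se if se is not None else DEFAULT_COST_SE_FRACTION * mean


def default_distributions(config: ModelConfig) -> list[ParamDistribution]:
    """Conventional PSA distributions derived from the configuration."""
    dists: list[ParamDistribution] = []
    util = config.utilities
    dists.append(
        ParamDistribution(
            "utilities.baseline.mean", "beta", util.baseline.mean, util.baseline.se
        )
    )
    for group, entries in (
        ("states", util.state_decrements),
        ("injections", util.injections),
    ):
        for key, entry in entries.items():
            if entry.mean == 0.0 or not entry.se:
                continue
            dists.append(
                ParamDistribution(
                    f"utilities.{group}.{key}.mean",
                    "beta",
                    entry.mean,
                    entry.se,
                    sign=-1,
                )
            )
    for name in ("age_per_10_years", "female", "duration_per_10_years", "bmi_per_unit"):
        entry = getattr(util, name)
        if entry.mean != 0.0 and entry.se:
            dists.append(
                ParamDistribution(
                    f"utilities.demographic_{name}.mean", "beta", entry.mean,
                    entry.se, sign=-1,
                )
            )
    for name in ("hypo_nonsevere", "hypo_severe"):
        entry = getattr(util, name)
        if entry.mean != 0.0 and entry.se:
            dists.append(
                ParamDistribution(
                    f"utilities.{name}.mean", "beta", entry.mean, entry.se, sign=-1
                )
            )
    dists.append(
        ParamDistribution(
            "background_cost.mean",
            "gamma",
            config.background_cost.mean,
            _cost_se(config.background_cost.mean, config.background_cost.se),
        )
    )
    for key, entry in config.hypo_costs.items():
        if entry.mean > 0:
            dists.append(
                ParamDistribution(
                    f"hypo_costs.{key}.mean",
                    "gamma",
                    entry.mean,
                    _cost_se(entry.mean, entry.se),
                )
            )
    for state_id, entry in config.costs.items():
        if entry.event_cost > 0:
            dists.append(
                ParamDistribution(
                    f"costs.{state_id}.event_cost",
                    "gamma",
                    entry.event_cost,
                    _cost_se(entry.event_cost, entry.event_cost_se),
                )
            )
        if entry.state_cost > 0:
            dists.append(
                ParamDistribution(
                    f"costs.{state_id}.state_cost",
                    "gamma",
                    entry.state_cost,
                    _cost_se(entry.state_cost, entry.state_cost_se),
                )
            )
    for name, effect in config.treatment_effects.items():
        if effect.low is None or effect.high is None:
            dists.append(
                ParamDistribution(f"{EFFECT_PREFIX}{name}", "fixed", effect.mean)
            )
        else:
            dists.append(
                ParamDistribution(
                    f"{EFFECT_PREFIX}{name}",
                    "normal",
                    effect.mean,
                    normal_sd_from_ci(effect.low, effect.high),
                )
            )
    return sorted(dists, key=lambda d: d.path)


_DEMOGRAPHIC_ALIASES = {
    "utilities.demographic_age_per_10_years.mean": "utilities.age_per_10_years.mean",
    "utilities.demographic_female.mean": "utilities.female.mean",
    "utilities.demographic_duration_per_10_years.mean":
        "utilities.duration_per_10_years.mean",
    "utilities.demographic_bmi_per_unit.mean": "utilities.bmi_per_unit.mean",
}


def _apply_value(config: ModelConfig, path: str, value: float) -> None:
    path = _DEMOGRAPHIC_ALIASES.get(path, path)
    if path.startswith(EFFECT_PREFIX):
        name = path[len(EFFECT_PREFIX):]
        comp = config.arm_comparator
        interv = config.arm_intervention
        if name == "hba1c_diff":
            interv.hba1c_on_treatment = comp.hba1c_on_treatment + value
        elif name == "bmi_diff":
            interv.bmi_on_treatment = comp.bmi_on_treatment + value
        elif name == "sbp_diff":
            interv.sbp_on_treatment = comp.sbp_on_treatment + value
        elif name == "dbp_diff":
            interv.dbp_on_treatment = comp.dbp_on_treatment + value
        elif name == "hypo_rr":
            rr = max(value, 0.0)
            interv.hypo_nonsevere_rate = comp.hypo_nonsevere_rate * rr
            interv.hypo_severe_rate = comp.hypo_severe_rate * rr
        else:
            raise ConfigError(f"unknown treatment effect {name!r}")
    else:
        set_by_path(config, path, value)


# ---------------------------------------------------------------------------
# one-way sensitivity (tornado)
# ---------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    parameter: str
    low: float
    high: float
    nmb_low: float | None = None
    nmb_high: float | None = None
    icer_low: float | None = None
    icer_high: float | None = None
    error: str | None = None

    @property
    def width(self) -> float:
        if self.nmb_low is None or self.nmb_high is None:
            return 0.0
        return abs(self.nmb_high - self.nmb_low)


def default_owsa_ranges(config: ModelConfig) -> list[tuple[str, float, float]]:
    """Default bounds: discount rates on [0, 0.08]; everything else +/-10%."""
    ranges: list[tuple[str, float, float]] = [
        ("econ.discount_rate_cost", 0.0, 0.08),
        ("econ.discount_rate_qaly", 0.0, 0.08),
    ]

    def pm10(path: str) -> None:
        base = get_by_path(config, path)
        if base == 0:
            return
        lo, hi = sorted((0.9 * base, 1.1 * base))
        ranges.append((path, lo, hi))

    for arm in ("arm_intervention", "arm_comparator",
                "switch_rule.post_switch_strategy"):
        for f in ("drug_cost_daily", "needle_cost_daily", "smbg_cost_daily",
                  "hypo_nonsevere_rate", "hypo_severe_rate", "hba1c_on_treatment"):
            pm10(f"{arm}.{f}")
    pm10("hba1c_drift_per_year")
    pm10("background_cost.mean")
    for key in config.hypo_costs:
        pm10(f"hypo_costs.{key}.mean")
    for state_id, entry in config.costs.items():
        if entry.event_cost:
            pm10(f"costs.{state_id}.event_cost")
        if entry.state_cost:
            pm10(f"costs.{state_id}.state_cost")
    base_u = get_by_path(config, "utilities.baseline.mean")
    ranges.append(
        ("utilities.baseline.mean", 0.9 * base_u, min(1.1 * base_u, 1.0))
    )
    for state_id, entry in config.utilities.state_decrements.items():
        if entry.mean:
            pm10(f"utilities.states.{state_id}.mean")
    for n, entry in config.utilities.injections.items():
        if entry.mean:
            pm10(f"utilities.injections.{n}.mean")
    for name in ("hypo_nonsevere", "hypo_severe"):
        pm10(f"utilities.{name}.mean")
    return ranges


def _evaluate_bound(
    config: ModelConfig, path: str, value: float
) -> tuple[float, float | None]:
    trial = copy.deepcopy(config)
    _apply_value(trial, path, value)
    trial.validate()
    result = run_ce_analysis(trial)
    return result.nmb, result.icer


def one_way_sensitivity(
    config: ModelConfig,
    ranges: list[tuple[str, float, float]] | None = None,
) -> list[TornadoEntry]:
    """One full deterministic model run per bound; entries sorted by width."""
    run_ce_analysis(config)  # base case must run before any excursion
    if ranges is None:
        ranges = default_owsa_ranges(config)
    entries: list[TornadoEntry] = []
    for path, low, high in ranges:
        entry = TornadoEntry(parameter=path, low=low, high=high)
        try:
            entry.nmb_low, entry.icer_low = _evaluate_bound(config, path, low)
            entry.nmb_high, entry.icer_high = _evaluate_bound(config, path, high)
        except (ConfigError, ValueError) as exc:
            entry.error = str(exc)
            logger.warning("OWSA bound failed for %s: %s", path, exc)
        entries.append(entry)
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PsaDraws:
    """Paired incremental outcomes from second-order parameter sampling."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    wtp: float
    parameter_records: list[dict[str, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.delta_cost)


def run_psa(
    config: ModelConfig,
    distributions: list[ParamDistribution] | None = None,
    n: int = 1000,
    seed: int = 0,
) -> PsaDraws:
    """Sample all parameters independently per draw and rerun both arms.

    Draw order is fixed by sorted parameter path, so adding a parameter does
    not silently reshuffle the randomness of the others.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if distributions is None:
        distributions = default_distributions(config)
    distributions = sorted(distributions, key=lambda d: d.path)
    for dist in distributions:  # pre-flight, before any simulation
        dist.validate()
    rng = np.random.default_rng(seed)
    delta_cost = np.empty(n)
    delta_qaly = np.empty(n)
    records: list[dict[str, float]] = []
    for i in range(n):
        sampled = {dist.path: dist.sample(rng) for dist in distributions}
        trial = copy.deepcopy(config)
        for path, value in sampled.items():
            _apply_value(trial, path, value)
        result = run_ce_analysis(trial)
        delta_cost[i] = result.delta_cost
        delta_qaly[i] = result.delta_qaly
        records.append(sampled)
    return PsaDraws(
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        seed=seed,
        wtp=config.econ.wtp_threshold,
        parameter_records=records,
    )


def ceac(
    draws: PsaDraws, thresholds: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """P(cost-effective) = fraction of draws with positive NMB, per threshold."""
    if draws.n == 0:
        raise ValueError("no PSA draws")
    if thresholds is None:
        thresholds = np.linspace(0.0, 3.0 * draws.wtp, 61)
    thresholds = np.asarray(thresholds, dtype=float)
    nmb = thresholds[:, None] * draws.delta_qaly[None, :] - draws.delta_cost[None, :]
    return thresholds, (nmb > 0).mean(axis=1)
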