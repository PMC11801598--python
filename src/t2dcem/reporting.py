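"""Assembly of the deterministic and probabilistic output tables.

Canonical outputs are plain CSV (UTF-8, '.' decimal, no thousands
separators); the human-readable summary is a convenience layer on top.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort_engine import (
    SimulationResult,
    cumulative_incidence,
    relative_risk,
    run_cohort,
)
from .economics import CEResult, EconomicLedger, build_ledger, summarize_ce
from .parameters import ModelConfig
from .uncertainty import PsaDraws, TornadoEntry, ceac

__all__ = [
    "ReportBundle",
    "config_hash",
    "build_incidence_table",
    "build_cost_table",
    "build_base_case_table",
    "tornado_table",
    "psa_scatter_table",
    "ceac_table",
    "run_base_case",
]

#: category grouping used in the base-case summary table
MICROVASCULAR_CATEGORIES = ("eye", "lower_extremity", "kidney")
MACROVASCULAR_CATEGORIES = ("ihd", "mi", "stroke", "heart_failure")
TREATMENT_CATEGORIES = ("treatment", "background", "hypoglycemia")


def config_hash(config: ModelConfig) -> str:
    """Stable digest of the full parameterization (for run metadata)."""
    canonical = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    incidence_table: pd.DataFrame
    cost_table: pd.DataFrame
    base_case_table: pd.DataFrame
    metadata: dict
    ce_result: CEResult
    results: dict[str, SimulationResult]
    ledgers: dict[str, EconomicLedger]
    tornado: pd.DataFrame | None = None
    psa_scatter: pd.DataFrame | None = None
    ceac_curve: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.incidence_table.to_csv(out / "incidence.csv", index=False)
        self.cost_table.to_csv(out / "costs.csv", index=False)
        self.base_case_table.to_csv(out / "base_case.csv", index=False)
        if self.tornado is not None:
            self.tornado.to_csv(out / "tornado.csv", index=False)
        if self.psa_scatter is not None:
            self.psa_scatter.to_csv(out / "psa_scatter.csv", index=False)
        if self.ceac_curve is not None:
            self.ceac_curve.to_csv(out / "ceac.csv", index=False)
        with (out / "metadata.yaml").open("w") as handle:
            yaml.safe_dump(self.metadata, handle, sort_keys=True)


def build_incidence_table(
    res_int: SimulationResult,
    res_comp: SimulationResult,
    config: ModelConfig,
) -> pd.DataFrame:
    rows = []

    def add(label: str, ci_i: float, ci_c: float) -> None:
        rows.append(
            {
                "outcome": label,
                "intervention_pct": round(ci_i, 2),
                "comparator_pct": round(ci_c, 2),
                "relative_risk": relative_risk(ci_i, ci_c) if ci_c else float("nan"),
            }
        )

    add(
        "cumulative_mortality",
        100.0 * res_int.cumulative_mortality,
        100.0 * res_comp.cumulative_mortality,
    )
    add(
        "cardiovascular_mortality",
        100.0 * res_int.cumulative_cv_mortality,
        100.0 * res_comp.cumulative_cv_mortality,
    )
    for sm in config.submodels:
        for state in sm.states[1:]:
            add(
                state,
                cumulative_incidence(res_int, state),
                cumulative_incidence(res_comp, state),
            )
    return pd.DataFrame(rows)


def build_cost_table(
    int_ledger: EconomicLedger, comp_ledger: EconomicLedger
) -> pd.DataFrame:
    int_totals = int_ledger.discounted_category_totals()
    comp_totals = comp_ledger.discounted_category_totals()
    rows = []
    for category in int_totals:
        i, c = int_totals[category], comp_totals[category]
        rows.append(
            {
                "category": category,
                "intervention": round(i),
                "comparator": round(c),
                "increment": round(i - c),
            }
        )
    i, c = int_ledger.total_cost_discounted, comp_ledger.total_cost_discounted
    rows.append(
        {
            "category": "total",
            "intervention": round(i),
            "comparator": round(c),
            "increment": round(i - c),
        }
    )
    return pd.DataFrame(rows)


def _grouped_cost(ce: CEResult, arm: str, categories: tuple[str, ...]) -> float:
    by_cat = ce.costs_by_category[arm]
    return sum(by_cat.get(cat, 0.0) for cat in categories)


def build_base_case_table(ce: CEResult) -> pd.DataFrame:
    rows = [
        {
            "metric": "life_expectancy_years",
            "intervention": round(ce.life_years["intervention"], 3),
            "comparator": round(ce.life_years["comparator"], 3),
            "increment": round(ce.delta_life_years, 3),
        },
        {
            "metric": "qalys",
            "intervention": round(ce.qalys["intervention"], 3),
            "comparator": round(ce.qalys["comparator"], 3),
            "increment": round(ce.delta_qaly, 3),
        },
        {
            "metric": "total_cost",
            "intervention": round(ce.costs_total["intervention"]),
            "comparator": round(ce.costs_total["comparator"]),
            "increment": round(ce.delta_cost),
        },
    ]
    for label, cats in (
        ("treatment_cost", TREATMENT_CATEGORIES),
        ("microvascular_cost", MICROVASCULAR_CATEGORIES),
        ("macrovascular_cost", MACROVASCULAR_CATEGORIES),
    ):
        i = _grouped_cost(ce, "intervention", cats)
        c = _grouped_cost(ce, "comparator", cats)
        rows.append(
            {
                "metric": label,
                "intervention": round(i),
                "comparator": round(c),
                "increment": round(i - c),
            }
        )
    rows.append(
        {
            "metric": "icer",
            "intervention": "",
            "comparator": "",
            "increment": ce.verdict_label,
        }
    )
    return pd.DataFrame(rows)


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_value": e.low,
                "high_value": e.high,
                "nmb_low": e.nmb_low,
                "nmb_high": e.nmb_high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "width": e.width,
                "error": e.error or "",
            }
            for e in entries
        ]
    )


def psa_scatter_table(draws: PsaDraws) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "draw": range(draws.n),
            "delta_qaly": draws.delta_qaly,
            "delta_cost": draws.delta_cost,
        }
    )


def ceac_table(draws: PsaDraws, thresholds=None) -> pd.DataFrame:
    grid, prob = ceac(draws, thresholds)
    return pd.DataFrame({"threshold": grid, "probability": prob})


def run_base_case(config: ModelConfig, seed: int | None = None) -> ReportBundle:
    """Run both arms plus economics and assemble all deterministic tables."""
    res_int = run_cohort(config, "intervention")
    res_comp = run_cohort(config, "comparator")
    int_ledger = build_ledger(res_int, config)
    comp_ledger = build_ledger(res_comp, config)
    ce = summarize_ce(int_ledger, comp_ledger, config.econ)
    metadata = {
        "config_hash": config_hash(config),
        "seed": seed,
        "horizon_years": config.econ.horizon_years,
        "verdict": ce.verdict_label,
    }
    return ReportBundle(
        incidence_table=build_incidence_table(res_int, res_comp, config),
        cost_table=build_cost_table(int_ledger, comp_ledger),
        base_case_table=build_base_case_table(ce),
        metadata=metadata,
        ce_result=ce,
        results={"intervention": res_int, "comparator": res_comp},
        ledgers={"intervention": int_ledger, "comparator": comp_ledger},
    )
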