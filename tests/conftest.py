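"""Shared fixtures: the bundled parameter set (fresh copy per test), cached
base-case runs, and a factory for minimal toy-sub-model configurations."""

from __future__ import annotations

import copy

import pytest

from t2dcem.cohort_engine import MarkovSubModelSpec, run_cohort
from t2dcem.economics import build_ledger, summarize_ce
from t2dcem.parameters import (
    CohortProfile,
    EconomicSettings,
    ModelConfig,
    SwitchRule,
    TreatmentStrategy,
    UtilityCatalog,
    ValueSE,
    default_paper_config,
)
from t2dcem.risk_equations import RiskEquationSpec


@pytest.fixture(scope="session")
def _paper_config_session() -> ModelConfig:
    return default_paper_config()


@pytest.fixture()
def paper_config(_paper_config_session: ModelConfig) -> ModelConfig:
    """Fresh mutable copy of the bundled default configuration."""
    return copy.deepcopy(_paper_config_session)


@pytest.fixture(scope="session")
def paper_results(_paper_config_session: ModelConfig) -> dict:
    """Both arms of the default parameterization, run once per session."""
    return {
        arm: run_cohort(_paper_config_session, arm)
        for arm in ("intervention", "comparator")
    }


@pytest.fixture(scope="session")
def paper_ledgers(_paper_config_session: ModelConfig, paper_results: dict) -> dict:
    return {
        arm: build_ledger(result, _paper_config_session)
        for arm, result in paper_results.items()
    }


@pytest.fixture(scope="session")
def paper_ce(_paper_config_session: ModelConfig, paper_ledgers: dict):
    return summarize_ce(
        paper_ledgers["intervention"],
        paper_ledgers["comparator"],
        _paper_config_session.econ,
    )


def _flat_strategy(name: str = "flat") -> TreatmentStrategy:
    return TreatmentStrategy(
        name=name,
        hba1c_on_treatment=7.0,
        bmi_on_treatment=30.0,
        sbp_on_treatment=120.0,
        dbp_on_treatment=80.0,
        hypo_nonsevere_rate=0.0,
        hypo_severe_rate=0.0,
        drug_cost_daily=0.0,
        needle_cost_daily=0.0,
        smbg_cost_daily=0.0,
        injections_per_day=0,
    )


def _minimal_utilities(state_decrements: dict[str, ValueSE] | None = None):
    zero = lambda: ValueSE(0.0, None)  # noqa: E731
    return UtilityCatalog(
        baseline=ValueSE(0.9, 0.05),
        bmi_anchor=30.0,
        age_per_10_years=zero(),
        female=zero(),
        duration_per_10_years=zero(),
        bmi_per_unit=zero(),
        state_decrements=state_decrements or {},
        hypo_nonsevere=zero(),
        hypo_severe=zero(),
        injections={},
    )


def make_config(
    submodels: list[MarkovSubModelSpec],
    equations: dict[str, RiskEquationSpec],
    horizon: int = 10,
    costs: dict | None = None,
    cost_categories: dict | None = None,
    state_decrements: dict | None = None,
    discount: float = 0.0,
) -> ModelConfig:
    """Minimal runnable configuration around externally supplied sub-models."""
    config = ModelConfig(
        cohort=CohortProfile(
            age_years=60.0,
            duration_years=10.0,
            prop_female=0.5,
            prop_smoker=0.2,
            hba1c_pct=7.0,
            sbp_mmHg=120.0,
            dbp_mmHg=80.0,
            tc_mmol=4.5,
            ldl_mmol=2.5,
            hdl_mmol=1.2,
            tg_mmol=1.8,
            bmi=30.0,
            heart_rate_bpm=70.0,
            wbc=6.0,
            egfr=80.0,
        ),
        arm_intervention=_flat_strategy("toy_intervention"),
        arm_comparator=_flat_strategy("toy_comparator"),
        switch_rule=SwitchRule(
            hba1c_threshold_pct=99.0, post_switch_strategy=_flat_strategy("toy_post")
        ),
        submodels=submodels,
        costs=costs or {},
        background_cost=ValueSE(0.0, None),
        hypo_costs={"nonsevere": ValueSE(0.0, None), "severe": ValueSE(0.0, None)},
        utilities=_minimal_utilities(state_decrements),
        econ=EconomicSettings(
            horizon_years=horizon,
            discount_rate_cost=discount,
            discount_rate_qaly=discount,
            wtp_threshold=10000.0,
        ),
        hba1c_drift_per_year=0.0,
        mortality=None,
        history_covariates={},
        cost_categories=cost_categories or {},
        risk_coefficients="builtin:risk_coefficients.csv",
    )
    config._equations = dict(equations)
    config.validate()
    return config
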