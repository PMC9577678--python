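"""Shared fixtures: toy person tables, a small two-stratum population spec,
and session-scoped calibrated runs reused by the calibration and headline
reproduction tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mtmsim as m
from mtmsim.population import DIAGNOSIS_COLUMNS, PERSON_COLUMNS


def make_person(
    person_id: str,
    weight: float = 1.0,
    payer: str = "medicare",
    expenditure: float = 10_000.0,
    hospitalizations: int = 0,
    diagnoses: tuple[str, ...] = (),
    iadl: bool = False,
    food_insecure: bool = False,
) -> dict:
    row = {
        "person_id": person_id,
        "weight": weight,
        "payer": payer,
        "annual_expenditure": expenditure,
        "annual_hospitalizations": hospitalizations,
        "annual_ed_visits": 0,
        "age_years": 70.0,
        "sex": "female",
        "race_ethnicity": "nh_white",
        "census_region": "south",
        "iadl_limited": iadl,
        "food_insecure": food_insecure,
    }
    for col in DIAGNOSIS_COLUMNS:
        row[col] = col.removeprefix("dx_") in diagnoses
    return row


@pytest.fixture
def toy_six() -> pd.DataFrame:
    """Six hand-written records covering the eligibility combinations."""
    rows = [
        make_person("a", diagnoses=("diabetes",), iadl=True),
        make_person("b", diagnoses=("diabetes",), iadl=True),
        make_person("c", diagnoses=("diabetes",), iadl=False),
        make_person("d", diagnoses=(), iadl=True),
        make_person("e", diagnoses=(), iadl=False),
        make_person("f", diagnoses=("chf",), iadl=True, food_insecure=True),
    ]
    return pd.DataFrame(rows)[list(PERSON_COLUMNS)]


@pytest.fixture
def tiny_spec() -> m.PopulationSpec:
    """Small two-stratum population for fast engine tests."""
    return m.PopulationSpec(
        strata=(
            m.StratumSpec("private", 1_000_000, 20_000, 22_000, 0.5, 0.9),
            m.StratumSpec("medicare", 2_000_000, 30_000, 33_000, 0.6, 1.1),
        ),
        diagnosis_prevalences={"diabetes": 0.5, "chf": 0.3},
        food_insecurity_prevalence=0.25,
    )


@pytest.fixture
def tiny_records(tiny_spec) -> pd.DataFrame:
    return m.generate_population(tiny_spec, 2_000, seed=11)


@pytest.fixture(scope="session")
def default_config() -> m.ModelConfig:
    return m.load_config()


@pytest.fixture(scope="session")
def primary_records(default_config) -> pd.DataFrame:
    """50,000-record realization of the calibrated primary 2019 population."""
    return m.generate_population(default_config.population, 50_000, seed=20190101)


@pytest.fixture(scope="session")
def primary_mc(default_config, primary_records) -> m.SimulationResult:
    """Default full-coverage 1000-replicate run on the primary population."""
    return m.run_monte_carlo(
        primary_records,
        default_config.effects,
        default_config.costs,
        n_replicates=1000,
        seed=20190102,
    )


@pytest.fixture(scope="session")
def coverage50_mc(default_config, primary_records) -> m.SimulationResult:
    """Same run at 50% coverage with the same seed (paired with primary_mc)."""
    return m.run_monte_carlo(
        primary_records,
        default_config.effects,
        default_config.costs,
        n_replicates=1000,
        seed=20190102,
        coverage_fraction=0.5,
    )


@pytest.fixture
def degenerate_effects() -> dict[str, m.PooledEffect]:
    """Point-mass pooled effects at the central estimates."""
    return {
        "expenditure": m.PooledEffect(
            outcome="expenditure_pct_change", estimate=0.197,
            ci_low=0.197, ci_high=0.197, scale="percent_reduction",
        ),
        "hospitalization": m.PooledEffect(
            outcome="hospitalization_rr", estimate=0.470,
            ci_low=0.470, ci_high=0.470, scale="percent_reduction",
        ),
    }


@pytest.fixture
def degenerate_costs() -> m.CostInputs:
    """Zero-variance cost inputs at the calibrated central values."""
    return m.CostInputs(
        screening_cost_low=31.255,
        screening_cost_high=31.255,
        monthly_meal_cost_mean=487.60,
        monthly_meal_cost_sd=0.0,
    )
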