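"""Secondary populations, sensitivity scenarios, and break-even thresholds.

Scenarios rerun the one-year (or multi-year) engine with overrides: a
restricted eligible population (food-insecure only, diabetes only, congestive
heart failure only), partial coverage, a fixed percentile of the
expenditure-effect distribution, or alternative discounting/carryover.  A
shared seed across scenarios gives paired (replicate-wise comparable) runs.

Threshold solvers find, at central estimates of every other input, the
expenditure-effect size or per-meal price at which net policy cost is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import defaults
from .costs import CostDraw, CostInputs, meal_cost_to_monthly
from .engine import (
    EffectDraws,
    SimulationResult,
    run_monte_carlo,
    simulate_replicate,
)
from .pooling import PooledEffect
from .population import (
    EligibilityCriteria,
    PopulationSpec,
    apply_eligibility_filter,
    generate_population,
)
from .projection import GrowthModel, MultiYearResult, growth_models_from_spec, simulate_multi_year


class InfeasibleThresholdError(ValueError):
    """The break-even equation has no positive solution."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Overrides applied on top of the default one-year model."""

    name: str
    criteria: EligibilityCriteria | None = None
    population_spec_override: PopulationSpec | None = None
    coverage_fraction: float = 1.0
    effect_percentile: float | None = None
    discount_rate: float | None = None
    carryover_fraction: float | None = None
    horizon_years: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must lie in [0, 1]")
        if self.effect_percentile is not None and not 0.0 < self.effect_percentile < 100.0:
            raise ValueError("effect_percentile must lie in (0, 100)")


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even solution with its residual at the solution."""

    quantity: str
    break_even_value: float
    solver: str
    residual_net_cost: float


#: Named scenarios shipped with the package.
NAMED_SCENARIOS: dict[str, ScenarioConfig] = {
    "primary": ScenarioConfig(name="primary"),
    "food_insecure": ScenarioConfig(
        name="food_insecure",
        population_spec_override=None,  # resolved lazily to the 2017 population
    ),
    "diabetes_only": ScenarioConfig(
        name="diabetes_only",
        criteria=EligibilityCriteria(required_diagnoses=frozenset({"diabetes"})),
    ),
    "chf_only": ScenarioConfig(
        name="chf_only",
        criteria=EligibilityCriteria(required_diagnoses=frozenset({"chf"})),
    ),
    "coverage50": ScenarioConfig(name="coverage50", coverage_fraction=0.5),
}


#: Scenarios whose population is a separately calibrated spec (the restricted
#: subgroups have higher baseline utilization than a diagnosis-filtered slice
#: of the primary population, whose generator draws utilization independently
#: of the diagnosis flags).
_SCENARIO_POPULATIONS = {
    "food_insecure": "food_insecure_2017",
    "diabetes_only": "diabetes_only",
    "chf_only": "chf_only",
}


def build_scenario(name: str) -> ScenarioConfig:
    if name not in NAMED_SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(NAMED_SCENARIOS)}")
    cfg = NAMED_SCENARIOS[name]
    if name in _SCENARIO_POPULATIONS and cfg.population_spec_override is None:
        cfg = ScenarioConfig(
            name=name,
            criteria=cfg.criteria,
            population_spec_override=defaults.population_spec(_SCENARIO_POPULATIONS[name]),
        )
    return cfg


def run_scenario(
    config: ScenarioConfig,
    pooled_effects: Mapping[str, PooledEffect],
    cost_inputs: CostInputs,
    shared_seed: int = 0,
    records: pd.DataFrame | None = None,
    population: PopulationSpec | None = None,
    n_records: int = 50_000,
    n_replicates: int = 1000,
    growth: Mapping[str, GrowthModel] | None = None,
    bootstrap: bool = True,
) -> SimulationResult | MultiYearResult:
    """Run one named or ad-hoc scenario.

    The base person table is either provided, or generated from the scenario's
    population override (falling back to the shipped primary population) with
    a generation seed derived from ``shared_seed`` so that scenarios sharing a
    seed are paired.  Eligibility criteria, when present, filter the table
    before simulation (weights untouched).
    """
    spec = config.population_spec_override or population or defaults.population_spec()
    if records is None:
        gen_seed, sim_seed = _split_seed(shared_seed)
        records = generate_population(spec, n_records, gen_seed)
    else:
        _, sim_seed = _split_seed(shared_seed)
    if config.criteria is not None:
        records = apply_eligibility_filter(records, config.criteria)
    if records.empty:
        raise ValueError(f"scenario {config.name!r} leaves no eligible records")

    if config.effect_percentile is not None:
        return _percentile_point_run(
            config, records, pooled_effects, cost_inputs
        )

    if config.horizon_years > 1:
        return simulate_multi_year(
            records,
            growth or growth_models_from_spec(spec),
            pooled_effects,
            cost_inputs,
            years=config.horizon_years,
            discount_rate=config.discount_rate if config.discount_rate is not None else 0.03,
            carryover_fraction=config.carryover_fraction or 0.0,
            n_replicates=n_replicates,
            seed=sim_seed,
            coverage_fraction=config.coverage_fraction,
            bootstrap=bootstrap,
        )
    return run_monte_carlo(
        records,
        pooled_effects,
        cost_inputs,
        n_replicates=n_replicates,
        seed=sim_seed,
        coverage_fraction=config.coverage_fraction,
        bootstrap=bootstrap,
    )


def _split_seed(shared_seed: int) -> tuple[int, int]:
    """Derive (generation seed, simulation seed) from one master seed."""
    ss = np.random.SeedSequence(shared_seed)
    gen, sim = ss.generate_state(2) % (2**31)
    return int(gen), int(sim)


def _percentile_point_run(
    config: ScenarioConfig,
    records: pd.DataFrame,
    pooled_effects: Mapping[str, PooledEffect],
    cost_inputs: CostInputs,
) -> SimulationResult:
    """Deterministic run with the expenditure effect at a fixed percentile."""
    exp_eff = pooled_effects["expenditure"]
    q = float(
        stats.norm.ppf(config.effect_percentile / 100.0, exp_eff.estimate, exp_eff.se)
    )
    q = min(max(q, 0.0), 1.0)
    effects = EffectDraws(
        expenditure_reduction=q,
        hospitalization_reduction=pooled_effects["hospitalization"].estimate,
    )
    draw = CostDraw(
        screening_cost=cost_inputs.screening_cost_central,
        monthly_meal_cost=cost_inputs.monthly_meal_cost_mean,
    )
    frame = simulate_replicate(
        records, effects, draw, config.coverage_fraction, cost_inputs.months_of_meals
    )
    reps = frame.reset_index().assign(replicate=0)
    summary = pd.DataFrame(
        {
            f"{q_}_{s}": frame[q_]
            for q_ in frame.columns
            for s in ("mean", "ui_low", "ui_high")
        }
    )
    summary.index.name = "stratum"
    return SimulationResult(
        replicates=reps,
        summary=summary,
        n_replicates=1,
        seed=None,
        fraction_cost_saving=float(frame.loc["total", "net_savings"] > 0),
        coverage_fraction=config.coverage_fraction,
    )


def effect_percentile_sweep(
    percentiles: Sequence[float],
    pooled_expenditure: PooledEffect,
    baseline_expenditures_total: float,
    program_cost_central: float,
) -> pd.DataFrame:
    """Deterministic net savings at fixed percentiles of the expenditure effect.

    All other inputs are held at their central estimates, so net savings is
    linear (hence monotone non-decreasing) in the effect quantile.
    """
    rows = []
    for p in percentiles:
        if not 0.0 < p < 100.0:
            raise ValueError(f"percentile {p} outside (0, 100)")
        q = float(
            stats.norm.ppf(p / 100.0, pooled_expenditure.estimate, pooled_expenditure.se)
        )
        q = min(max(q, 0.0), 1.0)
        rows.append(
            {
                "percentile": p,
                "expenditure_reduction": q,
                "averted_expenditures": q * baseline_expenditures_total,
                "net_savings": q * baseline_expenditures_total - program_cost_central,
            }
        )
    return pd.DataFrame(rows)


def break_even_effect(
    program_cost_central: float,
    baseline_expenditures_total: float,
    solver: str = "closed_form",
) -> ThresholdResult:
    """Minimum expenditure-reduction fraction at which net policy cost is zero."""
    if baseline_expenditures_total <= 0:
        raise ValueError("baseline_expenditures_total must be > 0")
    if solver == "closed_form":
        value = program_cost_central / baseline_expenditures_total
    elif solver == "bisection":
        f = lambda e: e * baseline_expenditures_total - program_cost_central
        hi = 1.0
        while f(hi) < 0:  # program cost may exceed total expenditures
            hi *= 2.0
        value = float(optimize.brentq(f, 0.0, hi, xtol=1e-12))
    else:
        raise ValueError(f"unknown solver {solver!r}")
    residual = value * baseline_expenditures_total - program_cost_central
    return ThresholdResult(
        quantity="expenditure_effect",
        break_even_value=float(value),
        solver=solver,
        residual_net_cost=float(residual),
    )


def break_even_meal_cost(
    savings_central: float,
    n_covered: float,
    months: float,
    screening_cost: float,
    cost_inputs: CostInputs,
    solver: str = "closed_form",
) -> ThresholdResult:
    """Per-meal price at which program cost equals the central averted savings.

    Monthly contract cost scales linearly with the per-meal price, anchored at
    the calibrated (per-meal mean, monthly mean) pair.  Infeasible when the
    savings cannot even cover screening.
    """
    if n_covered <= 0 or months <= 0:
        raise ValueError("n_covered and months must be > 0")
    per_person_savings = savings_central / n_covered
    if per_person_savings <= screening_cost:
        raise InfeasibleThresholdError(
            "no positive per-meal price: savings do not cover screening costs"
        )

    def cost_at(m: float) -> float:
        return n_covered * (months * meal_cost_to_monthly(m, cost_inputs) + screening_cost)

    if solver == "closed_form":
        value = (
            cost_inputs.per_meal_cost_mean
            * (per_person_savings - screening_cost)
            / (months * cost_inputs.monthly_meal_cost_mean)
        )
    elif solver == "bisection":
        f = lambda m: savings_central - cost_at(m)
        hi = cost_inputs.per_meal_cost_mean
        while f(hi) > 0:
            hi *= 2.0
        value = float(optimize.brentq(f, 0.0, hi, xtol=1e-12))
    else:
        raise ValueError(f"unknown solver {solver!r}")
    residual = cost_at(value) - savings_central
    return ThresholdResult(
        quantity="per_meal_cost",
        break_even_value=float(value),
        solver=solver,
        residual_net_cost=float(residual),
    )
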