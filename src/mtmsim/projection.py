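"""Ten-year open-cohort projection with discounting and optional carryover.

The eligible population is an open cohort: each projected year scales every
payer stratum's population by its fitted annual growth rate and per-patient
(inflation-adjusted) expenditures by its expenditure growth rate, holding
per-person hospitalization rates constant.  Growth rates come from log-linear
(OLS on log values) trend fits to historical yearly series.  Each year is
simulated independently with the one-year Monte Carlo engine; dollar flows
are discounted to present value at a fixed annual rate (base year
undiscounted), hospitalization counts are never discounted, and cumulative
totals sum replicate-wise across years.

An optional carryover scenario lets a fraction of each year's recipients
retain their expenditure reduction into the following year without receiving
(or paying for) meals in that year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .costs import CostInputs
from .engine import QUANTITIES, SimulationResult, run_monte_carlo, summarize_simulations
from .pooling import PooledEffect
from .population import PopulationSpec


@dataclass(frozen=True)
class GrowthModel:
    """Fitted annual growth rates for one payer stratum."""

    stratum: str
    annual_pop_growth: float
    annual_per_capita_expenditure_growth: float

    def __post_init__(self) -> None:
        for name in ("annual_pop_growth", "annual_per_capita_expenditure_growth"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")


@dataclass(frozen=True)
class MultiYearResult:
    """Per-year and cumulative outcomes over the projection horizon.

    ``per_year`` holds each year's :class:`SimulationResult` (dollar flows
    already discounted); ``cumulative_replicates``/``cumulative_summary``
    aggregate replicate-wise sums across years.
    """

    per_year: tuple[SimulationResult, ...]
    cumulative_replicates: pd.DataFrame
    cumulative_summary: pd.DataFrame
    horizon_years: int
    discount_rate: float
    carryover_fraction: float
    seed: int | None

    def total(self, quantity: str, stat: str = "mean") -> float:
        return float(self.cumulative_summary.loc["total", f"{quantity}_{stat}"])


def fit_loglinear_growth(series: Iterable[tuple[float, float]] | pd.DataFrame) -> float:
    """Annual growth rate from OLS of log(value) on year: exp(slope) - 1."""
    if isinstance(series, pd.DataFrame):
        pairs = list(zip(series.iloc[:, 0], series.iloc[:, 1]))
    else:
        pairs = list(series)
    if len(pairs) < 2:
        raise ValueError("fit_loglinear_growth requires at least 2 points")
    years = np.array([p[0] for p in pairs], dtype=float)
    values = np.array([p[1] for p in pairs], dtype=float)
    if (values <= 0).any():
        raise ValueError("all series values must be > 0 for a log-linear fit")
    X = sm.add_constant(years)
    fit = sm.OLS(np.log(values), X).fit()
    return float(np.expm1(fit.params[1]))


def synthetic_trend_series(
    base_value: float,
    growth: float,
    start_year: int,
    end_year: int,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Yearly exponential-growth series with multiplicative lognormal noise.

    Emulates the historical national series (population size, per-capita
    expenditures) from which growth rates are fitted; used for parameter-
    recovery testing of :func:`fit_loglinear_growth`.
    """
    years = np.arange(start_year, end_year + 1)
    values = base_value * (1.0 + growth) ** (years - start_year)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values * np.exp(rng.normal(0.0, noise_sd, size=years.size))
    return pd.DataFrame({"year": years, "value": values})


def growth_models_from_spec(spec: PopulationSpec) -> dict[str, GrowthModel]:
    """Growth models carried on a population spec's strata."""
    return {
        s.payer: GrowthModel(
            stratum=s.payer,
            annual_pop_growth=s.pop_growth_rate,
            annual_per_capita_expenditure_growth=s.per_capita_expenditure_growth_rate,
        )
        for s in spec.strata
    }


def project_year(
    base_population: PopulationSpec,
    growth: Mapping[str, GrowthModel],
    year_offset: int,
) -> PopulationSpec:
    """Population spec for base year + ``year_offset`` under compound growth.

    Stratum populations scale by (1+g_pop)^offset and mean/SD expenditures by
    (1+g_exp)^offset (constant coefficient of variation); hospitalization
    rates are held constant.
    """
    if year_offset < 0:
        raise ValueError("year_offset must be >= 0")
    pop_f = {
        p: (1.0 + g.annual_pop_growth) ** year_offset for p, g in growth.items()
    }
    exp_f = {
        p: (1.0 + g.annual_per_capita_expenditure_growth) ** year_offset
        for p, g in growth.items()
    }
    return base_population.scaled(pop_f, exp_f)


def discount_value(amount: float, rate: float, year_offset: int) -> float:
    """Present value of ``amount`` accruing at ``year_offset`` (base year 0)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return amount / (1.0 + rate) ** year_offset


def _scale_records(
    records: pd.DataFrame, growth: Mapping[str, GrowthModel], year_offset: int
) -> pd.DataFrame:
    out = records.copy()
    payers = out["payer"].to_numpy()
    pop_f = np.ones(len(out))
    exp_f = np.ones(len(out))
    for p, g in growth.items():
        mask = payers == p
        pop_f[mask] = (1.0 + g.annual_pop_growth) ** year_offset
        exp_f[mask] = (1.0 + g.annual_per_capita_expenditure_growth) ** year_offset
    out["weight"] = out["weight"].to_numpy() * pop_f
    out["annual_expenditure"] = out["annual_expenditure"].to_numpy() * exp_f
    return out


_DOLLAR_QUANTITIES = ("averted_expenditures", "program_cost", "net_savings")


def simulate_multi_year(
    records: pd.DataFrame,
    growth: Mapping[str, GrowthModel],
    pooled_effects: Mapping[str, PooledEffect],
    cost_inputs: CostInputs,
    years: int = 10,
    discount_rate: float = 0.03,
    carryover_fraction: float = 0.0,
    n_replicates: int = 1000,
    seed: int | None = 0,
    coverage_fraction: float = 1.0,
    months_of_meals: float | None = None,
    bootstrap: bool = True,
) -> MultiYearResult:
    """Open-cohort multi-year simulation over a base-year person table.

    The base-year table realizes the eligible population; each later year
    rescales record weights and expenditures by the stratum growth rates and
    reruns the one-year Monte Carlo with its own derived seed.  Dollar flows
    of year t are discounted by 1/(1+rate)^t.  With ``carryover_fraction``
    f > 0, year t >= 1 additionally averts f x the previous year's
    (undiscounted) averted expenditures, at no meal cost, discounted at year
    t's factor.  ``carryover_fraction = 0`` reproduces the base run exactly
    for the same seed.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if not 0.0 <= carryover_fraction <= 1.0:
        raise ValueError("carryover_fraction must lie in [0, 1]")
    master = np.random.default_rng(seed)
    year_seeds = master.integers(0, 2**31, size=years)
    if isinstance(seed, (int, np.integer)):
        # Year 0 reuses the caller's seed so a 1-year horizon reproduces the
        # one-year engine exactly.
        year_seeds[0] = seed

    per_year: list[SimulationResult] = []
    raw_averted_exp: list[pd.Series] = []  # undiscounted, keyed (stratum, replicate)
    cumulative: pd.DataFrame | None = None
    for t in range(years):
        year_records = records if t == 0 else _scale_records(records, growth, t)
        res = run_monte_carlo(
            year_records,
            pooled_effects,
            cost_inputs,
            n_replicates=n_replicates,
            seed=int(year_seeds[t]),
            coverage_fraction=coverage_fraction,
            months_of_meals=months_of_meals,
            bootstrap=bootstrap,
        )
        reps = res.replicates.set_index(["stratum", "replicate"]).sort_index()
        raw_exp = reps["averted_expenditures"].copy()

        factor = 1.0 / (1.0 + discount_rate) ** t
        for q in _DOLLAR_QUANTITIES:
            reps[q] = reps[q] * factor
        if carryover_fraction > 0.0 and t >= 1:
            extra = carryover_fraction * raw_averted_exp[t - 1] * factor
            reps["averted_expenditures"] = reps["averted_expenditures"] + extra
            reps["net_savings"] = reps["net_savings"] + extra

        raw_averted_exp.append(raw_exp)
        year_reps = reps.reset_index()
        year_summary = summarize_simulations(year_reps)
        frac = float(
            (year_reps.loc[year_reps["stratum"] == "total", "net_savings"] > 0).mean()
        )
        per_year.append(
            SimulationResult(
                replicates=year_reps,
                summary=year_summary,
                n_replicates=n_replicates,
                seed=int(year_seeds[t]),
                fraction_cost_saving=frac,
                coverage_fraction=coverage_fraction,
            )
        )
        cumulative = reps if cumulative is None else cumulative + reps

    cum_reps = cumulative.reset_index()
    cum_summary = summarize_simulations(cum_reps)
    return MultiYearResult(
        per_year=tuple(per_year),
        cumulative_replicates=cum_reps,
        cumulative_summary=cum_summary,
        horizon_years=years,
        discount_rate=discount_rate,
        carryover_fraction=carryover_fraction,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def geometric_multiplier(growth: float, years: int) -> float:
    """Sum of (1+g)^t for t = 0..years-1 (closed-form open-cohort multiplier)."""
    if growth == 0:
        return float(years)
    return float(((1.0 + growth) ** years - 1.0) / growth)
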