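"""Annual MTM program cost model: screening plus monthly meal contracts.

Annual per-person cost = months_of_meals × monthly meal-contract cost + a
one-time clinical screening cost per covered person per year.  Screening is
drawn Uniform over the published geographic range of Medicare reimbursement
for an initial dietitian assessment; the monthly contract cost is Normal,
truncated at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CostInputs:
    """Cost parameters, all in 2019 USD."""

    screening_cost_low: float = 27.34
    screening_cost_high: float = 35.17
    monthly_meal_cost_mean: float = 487.60
    monthly_meal_cost_sd: float = 34.7
    months_of_meals: float = 8.0
    per_meal_cost_mean: float = 9.30
    per_meal_cost_sd: float = 0.64

    def __post_init__(self) -> None:
        for name in (
            "screening_cost_low",
            "screening_cost_high",
            "monthly_meal_cost_mean",
            "monthly_meal_cost_sd",
            "per_meal_cost_mean",
            "per_meal_cost_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.screening_cost_low > self.screening_cost_high:
            raise ValueError("screening_cost_low must be <= screening_cost_high")
        if not 0.0 < self.months_of_meals <= 12.0:
            raise ValueError("months_of_meals must lie in (0, 12]")

    @property
    def screening_cost_central(self) -> float:
        return 0.5 * (self.screening_cost_low + self.screening_cost_high)

    def annual_cost_per_person(
        self,
        monthly_meal_cost: float | None = None,
        screening_cost: float | None = None,
    ) -> float:
        """Central (or overridden) annual program cost for one covered person."""
        monthly = self.monthly_meal_cost_mean if monthly_meal_cost is None else monthly_meal_cost
        screening = self.screening_cost_central if screening_cost is None else screening_cost
        return self.months_of_meals * monthly + screening


@dataclass(frozen=True)
class CostDraw:
    """One Monte Carlo realization of the cost inputs."""

    screening_cost: float
    monthly_meal_cost: float

    def __post_init__(self) -> None:
        if self.screening_cost < 0 or self.monthly_meal_cost < 0:
            raise ValueError("cost draws must be >= 0")


def draw_costs(inputs: CostInputs, rng: np.random.Generator) -> CostDraw:
    """Draw screening ~ Uniform(low, high), monthly ~ Normal truncated at 0."""
    screening = float(rng.uniform(inputs.screening_cost_low, inputs.screening_cost_high))
    monthly = float(
        draw_monthly_meal_costs(inputs, rng, size=1)[0]
    )
    return CostDraw(screening_cost=screening, monthly_meal_cost=monthly)


def draw_monthly_meal_costs(
    inputs: CostInputs, rng: np.random.Generator, size: int | tuple[int, ...]
) -> np.ndarray:
    """Vectorized truncated-normal monthly meal-contract cost draws."""
    mean, sd = inputs.monthly_meal_cost_mean, inputs.monthly_meal_cost_sd
    if sd == 0:
        return np.full(size, mean, dtype=float)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def compute_program_cost(
    n_covered: float, draw: CostDraw, months_of_meals: float
) -> float:
    """Annual program cost: n × (months × monthly meal cost + screening)."""
    if n_covered < 0:
        raise ValueError("n_covered must be >= 0")
    return n_covered * (months_of_meals * draw.monthly_meal_cost + draw.screening_cost)


def meal_cost_to_monthly(per_meal_cost: float, inputs: CostInputs) -> float:
    """Monthly contract cost implied by a per-meal price, by linear scaling
    anchored at (per_meal_cost_mean, monthly_meal_cost_mean)."""
    if per_meal_cost < 0:
        raise ValueError("per_meal_cost must be >= 0")
    if inputs.per_meal_cost_mean == 0:
        raise ValueError("per_meal_cost_mean must be nonzero to anchor the scaling")
    return inputs.monthly_meal_cost_mean * (per_meal_cost / inputs.per_meal_cost_mean)
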