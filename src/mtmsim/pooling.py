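"""Random-effects pooling of study-level MTM effect estimates.

Five published interventional studies of medically tailored meals contribute
estimates of (a) the relative risk of annual hospitalization, (b) the percent
change in annual health care expenditures, (c) per-meal cost, and (d) months
of meal receipt per patient-year.  Effects are combined by inverse-variance
random-effects meta-analysis with the DerSimonian–Laird moment estimator of
the between-study variance tau^2:

    w_i   = 1 / se_i^2                     (fixed-effect weights)
    Q     = sum w_i (y_i - ybar_FE)^2      (Cochran's Q)
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))
    w*_i  = 1 / (se_i^2 + tau^2)
    pooled = sum w*_i y_i / sum w*_i,  se = 1 / sqrt(sum w*_i)

with symmetric normal-approximation confidence intervals.  Hospitalization
effects are pooled on the log-risk-ratio scale and reported as a percent
reduction (1 - RR); expenditure effects are pooled directly on the
percent-change scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OUTCOMES = ("hospitalization_rr", "expenditure_pct_change", "per_meal_cost", "duration_months")


@dataclass(frozen=True)
class StudyRecord:
    """One study-level input on its declared scale."""

    study_id: str
    outcome: str
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    se: float | None = None
    n_participants: float | None = None
    duration_months: float | None = None
    scale: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low < self.ci_high:
                raise ValueError("ci_low must be < ci_high")
            if self.estimate is not None and not (
                self.ci_low < self.estimate < self.ci_high
            ):
                raise ValueError("estimate must lie strictly inside its CI")
        if self.se is not None and self.se <= 0:
            raise ValueError("se must be > 0")

    def resolved_se(self, level: float = 0.95) -> float:
        if self.se is not None:
            return self.se
        if self.ci_low is None or self.ci_high is None:
            raise ValueError(f"study {self.study_id!r} has neither se nor a CI")
        return se_from_ci(self.ci_low, self.ci_high, level)


@dataclass(frozen=True)
class PooledEffect:
    """Meta-analytic point estimate with CI and between-study variance."""

    outcome: str
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float = 0.0
    k: int = 1
    scale: str = "percent_reduction"

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("estimate must lie within [ci_low, ci_high]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def se(self) -> float:
        """Normal-approximation SE implied by the 95% CI (0 for a point CI)."""
        if self.ci_high == self.ci_low:
            return 0.0
        return se_from_ci(self.ci_low, self.ci_high)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def se_from_ci(ci_low: float, ci_high: float, level: float = 0.95) -> float:
    """Standard error implied by a symmetric normal-approximation CI."""
    if ci_high <= ci_low:
        raise ValueError(f"ci_high must exceed ci_low (got {ci_low}, {ci_high})")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (ci_high - ci_low) / (2.0 * z)


def pool_random_effects(
    studies: Sequence[StudyRecord], method: str = "dersimonian-laird"
) -> PooledEffect:
    """Inverse-variance random-effects pooling (DerSimonian–Laird tau^2)."""
    if method not in ("dersimonian-laird", "fixed"):
        raise ValueError(f"unknown pooling method {method!r}")
    studies = [s for s in studies if s.estimate is not None]
    if not studies:
        raise ValueError("pool_random_effects requires at least one study")
    scales = {s.scale for s in studies}
    if len(scales) > 1:
        raise ValueError(f"studies mix scales: {sorted(map(str, scales))}")
    outcomes = {s.outcome for s in studies}
    if len(outcomes) > 1:
        raise ValueError(f"studies mix outcomes: {sorted(outcomes)}")

    y = np.array([s.estimate for s in studies], dtype=float)
    se = np.array([s.resolved_se() for s in studies], dtype=float)
    k = len(y)

    w = 1.0 / se**2
    fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - fixed) ** 2))
    if method == "fixed" or k == 1:
        tau2 = 0.0
    else:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom)

    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    pooled_se = float(1.0 / math.sqrt(np.sum(w_star)))
    z = stats.norm.ppf(0.975)
    return PooledEffect(
        outcome=studies[0].outcome,
        estimate=pooled,
        ci_low=pooled - z * pooled_se,
        ci_high=pooled + z * pooled_se,
        tau2=tau2,
        k=k,
        scale=studies[0].scale or "unspecified",
    )


def weighted_mean_duration(studies: Iterable[StudyRecord]) -> float:
    """Participant-weighted mean months of MTM receipt per patient-year."""
    num = 0.0
    den = 0.0
    for s in studies:
        if s.duration_months is None:
            continue
        n = s.n_participants if s.n_participants is not None else 1.0
        num += n * s.duration_months
        den += n
    if den <= 0:
        raise ValueError("weighted_mean_duration requires positive total weight")
    return num / den


def pooled_meal_cost(studies: Sequence[StudyRecord]) -> tuple[float, float]:
    """Arithmetic mean and sample SD of per-meal costs across organizations."""
    costs = [s.estimate for s in studies if s.outcome == "per_meal_cost" and s.estimate is not None]
    if not costs:
        raise ValueError("pooled_meal_cost requires at least one per_meal_cost record")
    arr = np.asarray(costs, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


_STUDY_COLUMNS = (
    "study_id",
    "outcome",
    "scale",
    "estimate",
    "ci_low",
    "ci_high",
    "se",
    "n_participants",
    "duration_months",
)


def read_study_table(path) -> list[StudyRecord]:
    """Load study records from CSV (columns as in the shipped template)."""
    frame = pd.read_csv(path)
    missing = [c for c in ("study_id", "outcome") if c not in frame.columns]
    if missing:
        raise ValueError(f"study table missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col in _STUDY_COLUMNS:
            if col in frame.columns and pd.notna(row[col]):
                kwargs[col] = row[col]
        records.append(StudyRecord(**kwargs))
    return records
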