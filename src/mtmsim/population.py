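"""Synthetic cohorts of adults eligible for medically tailored meals (MTMs).

The modeled population is noninstitutionalized US adults covered by private
insurance, Medicare, Medicaid, or both ("dual eligible") who have at least one
diet-sensitive condition (diabetes, congestive heart failure, myocardial
infarction, other heart disease, stroke, cancer, emphysema, chronic kidney
disease, or HIV infection) and at least one limitation in instrumental
activities of daily living (IADLs).  Person-level records carry survey-style
weights so that weighted totals represent the national eligible population.

Annual expenditures are drawn from a right-skewed family (lognormal by
default, gamma as an alternative) moment-matched to each payer stratum's mean
and SD; hospitalization counts are negative binomial (variance exceeds the
mean in this population, which rules out Poisson).  The two are coupled
through a Gaussian copula because high-utilization patients drive both.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Diet-sensitive condition flags, in canonical column order.
DIAGNOSES: tuple[str, ...] = (
    "diabetes",
    "chf",
    "mi",
    "other_heart",
    "stroke",
    "cancer",
    "emphysema",
    "ckd",
    "hiv",
)

#: Recognized payer strata.
PAYERS: tuple[str, ...] = ("private", "medicare", "medicaid", "dual")

DIAGNOSIS_COLUMNS: tuple[str, ...] = tuple(f"dx_{d}" for d in DIAGNOSES)

#: Columns every person table must provide (flags stored as 0/1 on disk).
MANDATORY_COLUMNS: tuple[str, ...] = (
    "person_id",
    "weight",
    "payer",
    "annual_expenditure",
    "annual_hospitalizations",
    "iadl_limited",
    "food_insecure",
) + DIAGNOSIS_COLUMNS

#: Full canonical column order for generated tables.
PERSON_COLUMNS: tuple[str, ...] = (
    "person_id",
    "weight",
    "payer",
    "annual_expenditure",
    "annual_hospitalizations",
    "annual_ed_visits",
    "age_years",
    "sex",
    "race_ethnicity",
    "census_region",
    "iadl_limited",
    "food_insecure",
) + DIAGNOSIS_COLUMNS

_NUMERIC_COLUMNS = ("weight", "annual_expenditure", "annual_hospitalizations")
_FLAG_COLUMNS = ("iadl_limited", "food_insecure") + DIAGNOSIS_COLUMNS


class SchemaError(ValueError):
    """A person table is missing mandatory columns or has malformed rows."""


@dataclass(frozen=True)
class StratumSpec:
    """Calibration targets for one payer stratum.

    ``n_population`` is the weighted count of eligible persons the stratum
    represents; means/SDs are per person-year in base-year dollars.
    """

    payer: str
    n_population: float
    mean_expenditure: float
    sd_expenditure: float
    mean_hospitalizations: float
    sd_hospitalizations: float
    pop_growth_rate: float = 0.0
    per_capita_expenditure_growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_population <= 0:
            raise ValueError(f"n_population must be > 0 (stratum {self.payer!r})")
        for name in ("mean_expenditure", "sd_expenditure", "sd_hospitalizations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (stratum {self.payer!r})")
        if self.mean_hospitalizations < 0:
            raise ValueError(f"mean_hospitalizations must be >= 0 (stratum {self.payer!r})")
        for name in ("pop_growth_rate", "per_capita_expenditure_growth_rate"):
            g = getattr(self, name)
            if not -1.0 < g < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1) (stratum {self.payer!r})")


@dataclass(frozen=True)
class PopulationSpec:
    """Full calibration recipe for a synthetic eligible population."""

    strata: tuple[StratumSpec, ...]
    diagnosis_prevalences: Mapping[str, float]
    food_insecurity_prevalence: float = 0.0
    expenditure_distribution: str = "lognormal"
    hospitalization_distribution: str = "negative_binomial"
    utilization_correlation: float = 0.5
    mean_ed_visits: float = 0.98
    sd_ed_visits: float = 1.68
    age_mean: float = 68.1
    age_sd: float = 16.6
    sex_shares: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.634, "male": 0.366}
    )
    race_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "hispanic": 0.113,
            "nh_asian": 0.031,
            "nh_black": 0.142,
            "nh_white": 0.667,
            "other_multiple": 0.047,
        }
    )
    region_shares: Mapping[str, float] = field(
        default_factory=lambda: {
            "northeast": 0.178,
            "midwest": 0.202,
            "south": 0.394,
            "west": 0.226,
        }
    )
    base_year: int = 2019
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("PopulationSpec requires at least one stratum")
        payers = [s.payer for s in self.strata]
        if len(set(payers)) != len(payers):
            raise ValueError("duplicate payer strata")
        for flag, p in self.diagnosis_prevalences.items():
            if flag not in DIAGNOSES:
                raise ValueError(f"unknown diagnosis flag {flag!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"diagnosis_prevalences[{flag!r}] must lie in [0, 1]")
        if not 0.0 <= self.food_insecurity_prevalence <= 1.0:
            raise ValueError("food_insecurity_prevalence must lie in [0, 1]")
        if self.expenditure_distribution not in ("lognormal", "gamma"):
            raise ValueError(
                "expenditure_distribution must be 'lognormal' or 'gamma', "
                f"got {self.expenditure_distribution!r}"
            )
        if self.hospitalization_distribution != "negative_binomial":
            raise ValueError("hospitalization_distribution must be 'negative_binomial'")
        if not -1.0 < self.utilization_correlation < 1.0:
            raise ValueError("utilization_correlation must lie in (-1, 1)")

    @property
    def total_population(self) -> float:
        return float(sum(s.n_population for s in self.strata))

    def stratum(self, payer: str) -> StratumSpec:
        for s in self.strata:
            if s.payer == payer:
                return s
        raise KeyError(payer)

    def scaled(
        self,
        pop_factor: Mapping[str, float],
        expenditure_factor: Mapping[str, float],
    ) -> "PopulationSpec":
        """Return a copy with per-stratum population and expenditure scalings.

        SDs scale with the mean (constant coefficient of variation).
        """
        new = tuple(
            replace(
                s,
                n_population=s.n_population * pop_factor.get(s.payer, 1.0),
                mean_expenditure=s.mean_expenditure * expenditure_factor.get(s.payer, 1.0),
                sd_expenditure=s.sd_expenditure * expenditure_factor.get(s.payer, 1.0),
            )
            for s in self.strata
        )
        return replace(self, strata=new)


@dataclass(frozen=True)
class EligibilityCriteria:
    """Any-of diagnosis requirement plus optional IADL / food-insecurity gates."""

    required_diagnoses: frozenset[str] = frozenset(DIAGNOSES)
    require_iadl: bool = True
    require_food_insecurity: bool = False

    def __post_init__(self) -> None:
        if not self.required_diagnoses:
            raise ValueError("required_diagnoses must be non-empty")
        unknown = set(self.required_diagnoses) - set(DIAGNOSES)
        if unknown:
            raise ValueError(f"unknown diagnosis flags: {sorted(unknown)}")


def _largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``shares`` (sums exactly)."""
    raw = total * shares / shares.sum()
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def _adjusted_flag_rates(prevalences: Mapping[str, float]) -> dict[str, float]:
    """Bernoulli rates whose post-rejection (>=1 flag) prevalences hit targets.

    With independent flags and rejection of all-zero rows, the conditional
    prevalence of flag i is p_i / (1 - prod(1 - p_j)).  Solving
    p_i = t_i * q with q = 1 - prod(1 - t_i q) gives rates whose conditional
    prevalences equal the targets t_i exactly.  A nontrivial solution exists
    only when sum(t_i) > 1; otherwise targets are used unadjusted (rejection
    then inflates prevalences, which is unavoidable).
    """
    targets = np.array([prevalences.get(d, 0.0) for d in DIAGNOSES])
    if targets.sum() <= 1.0:
        return {d: prevalences.get(d, 0.0) for d in DIAGNOSES}
    q = 1.0
    for _ in range(200):
        q_new = 1.0 - np.prod(1.0 - targets * q)
        if abs(q_new - q) < 1e-13:
            q = q_new
            break
        q = q_new
    return {d: float(t * q) for d, t in zip(DIAGNOSES, targets)}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def lognormal_median(mean: float, sd: float) -> float:
    """Closed-form median of the moment-matched lognormal: mean / sqrt(1 + CV^2)."""
    mu, _ = _lognormal_params(mean, sd)
    return float(np.exp(mu))


def _negbin_params(mean: float, sd: float) -> tuple[float, float]:
    """(r, p) of a negative binomial with the given mean and SD.

    Requires overdispersion (sd^2 > mean).
    """
    var = sd * sd
    if var <= mean:
        raise ValueError(
            f"negative binomial requires variance > mean (got mean={mean}, sd={sd})"
        )
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return float(r), float(p)


def _draw_stratum(
    spec: PopulationSpec,
    stratum: StratumSpec,
    n: int,
    rng: np.random.Generator,
    flag_rates: Mapping[str, float],
) -> pd.DataFrame:
    rho = spec.utilization_correlation
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)

    if spec.expenditure_distribution == "lognormal":
        mu, sigma = _lognormal_params(stratum.mean_expenditure, stratum.sd_expenditure)
        expenditure = np.exp(mu + sigma * z1)
    else:  # gamma, moment matched
        var = stratum.sd_expenditure**2
        shape = stratum.mean_expenditure**2 / var
        scale = var / stratum.mean_expenditure
        expenditure = stats.gamma.ppf(stats.norm.cdf(z1), shape, scale=scale)

    r, p = _negbin_params(stratum.mean_hospitalizations, stratum.sd_hospitalizations)
    hospitalizations = stats.nbinom.ppf(stats.norm.cdf(z2), r, p).astype(int)

    r_ed, p_ed = _negbin_params(spec.mean_ed_visits, spec.sd_ed_visits)
    ed_visits = stats.nbinom.rvs(r_ed, p_ed, size=n, random_state=rng)

    # Diagnosis flags: independent Bernoulli at calibrated rates, with a
    # rejection loop forcing >= 1 flag per record (eligibility by construction).
    rates = np.array([flag_rates[d] for d in DIAGNOSES])
    flags = rng.random((n, len(DIAGNOSES))) < rates
    empty = ~flags.any(axis=1)
    while empty.any():
        flags[empty] = rng.random((int(empty.sum()), len(DIAGNOSES))) < rates
        empty = ~flags.any(axis=1)

    a = (18.0 - spec.age_mean) / spec.age_sd
    age = stats.truncnorm.rvs(
        a, np.inf, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng
    )

    def _choice(shares: Mapping[str, float]) -> np.ndarray:
        labels = list(shares)
        probs = np.array([shares[k] for k in labels], dtype=float)
        return rng.choice(labels, size=n, p=probs / probs.sum())

    frame = pd.DataFrame(
        {
            "weight": np.full(n, stratum.n_population / n),
            "payer": stratum.payer,
            "annual_expenditure": expenditure,
            "annual_hospitalizations": hospitalizations,
            "annual_ed_visits": ed_visits.astype(int),
            "age_years": age,
            "sex": _choice(spec.sex_shares),
            "race_ethnicity": _choice(spec.race_shares),
            "census_region": _choice(spec.region_shares),
            "iadl_limited": True,
            "food_insecure": rng.random(n) < spec.food_insecurity_prevalence,
        }
    )
    for col, d in zip(DIAGNOSIS_COLUMNS, DIAGNOSES):
        frame[col] = flags[:, DIAGNOSES.index(d)]
    return frame


def generate_population(
    spec: PopulationSpec, n_records: int, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """Draw a weighted synthetic person table calibrated to ``spec``.

    Records are allocated across payer strata proportionally to stratum
    population (largest-remainder rounding); within a stratum weights are
    uniform and scaled so they sum exactly to the stratum population, so total
    weight always equals ``spec.total_population`` regardless of ``n_records``.
    Identical ``seed`` yields an identical table.
    """
    if n_records < 0:
        raise ValueError("n_records must be >= 0")
    empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _EMPTY_DTYPES.items()})
    if n_records == 0:
        return empty

    rng = np.random.default_rng(seed)
    shares = np.array([s.n_population for s in spec.strata], dtype=float)
    counts = _largest_remainder(n_records, shares)
    flag_rates = _adjusted_flag_rates(spec.diagnosis_prevalences)

    parts = []
    for stratum, n in zip(spec.strata, counts):
        if n == 0:
            continue
        parts.append(_draw_stratum(spec, stratum, int(n), rng, flag_rates))
    table = pd.concat(parts, ignore_index=True)
    width = len(str(len(table)))
    table.insert(0, "person_id", [f"p{i:0{width}d}" for i in range(1, len(table) + 1)])
    return table[list(PERSON_COLUMNS)]


_EMPTY_DTYPES: dict[str, str] = {
    "person_id": "object",
    "weight": "float64",
    "payer": "object",
    "annual_expenditure": "float64",
    "annual_hospitalizations": "int64",
    "annual_ed_visits": "int64",
    "age_years": "float64",
    "sex": "object",
    "race_ethnicity": "object",
    "census_region": "object",
    "iadl_limited": "bool",
    "food_insecure": "bool",
    **{c: "bool" for c in DIAGNOSIS_COLUMNS},
}


def apply_eligibility_filter(
    records: pd.DataFrame, criteria: EligibilityCriteria
) -> pd.DataFrame:
    """Rows satisfying (any required diagnosis) AND the boolean gates.

    Order and weights are preserved; the result is a copy.
    """
    if records.empty:
        return records.copy()
    cols = [f"dx_{d}" for d in sorted(criteria.required_diagnoses)]
    mask = records[cols].any(axis=1)
    if criteria.require_iadl:
        mask &= records["iadl_limited"].astype(bool)
    if criteria.require_food_insecurity:
        mask &= records["food_insecure"].astype(bool)
    return records.loc[mask].copy()


def write_person_table(records: pd.DataFrame, path) -> None:
    """Write a person table as CSV with flag columns encoded 0/1."""
    out = records.copy()
    for col in _FLAG_COLUMNS:
        if col in out.columns:
            out[col] = out[col].astype(bool).astype(int)
    out.to_csv(path, index=False)


def read_person_table(path) -> pd.DataFrame:
    """Read a person-table CSV written by :func:`write_person_table`.

    Mandatory columns are validated up front; unknown columns are dropped with
    a logged warning; flags come back as booleans.
    """
    raw = pd.read_csv(path, dtype={"person_id": str, "payer": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"person table missing mandatory columns: {missing}")
    unknown = [c for c in raw.columns if c not in PERSON_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown person-table columns: %s", unknown)
        raw = raw.drop(columns=unknown)
    for col in _NUMERIC_COLUMNS:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"non-numeric value in column {col!r} at row {row}: {raw[col][row]!r}"
            )
        raw[col] = converted
    raw["annual_hospitalizations"] = raw["annual_hospitalizations"].astype(int)
    if "annual_ed_visits" in raw.columns:
        raw["annual_ed_visits"] = raw["annual_ed_visits"].astype(int)
    for col in _FLAG_COLUMNS:
        raw[col] = raw[col].astype(int).astype(bool)
    ordered = [c for c in PERSON_COLUMNS if c in raw.columns]
    return raw[ordered]


def _weighted_quantile(
    values: np.ndarray, weights: np.ndarray, q: float | Sequence[float]
) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return np.interp(np.atleast_1d(q), cum, v)


def population_summary(records: pd.DataFrame) -> pd.Series:
    """Weighted descriptive statistics of a person table.

    Returns a Series keyed by statistic name: weighted N, mean/SD and
    median/IQR of expenditures, hospitalizations and ED visits, payer-stratum
    shares, and diagnosis prevalences.  SDs are weighted population SDs.
    """
    if records.empty:
        raise ValueError("population_summary requires a non-empty person table")
    w = records["weight"].to_numpy(float)
    total = w.sum()
    out: dict[str, float] = {"weighted_n": total}

    for col, label in (
        ("annual_expenditure", "expenditure"),
        ("annual_hospitalizations", "hospitalizations"),
        ("annual_ed_visits", "ed_visits"),
    ):
        if col not in records.columns:
            continue
        x = records[col].to_numpy(float)
        mean = float(np.average(x, weights=w))
        sd = float(np.sqrt(np.average((x - mean) ** 2, weights=w)))
        q25, q50, q75 = _weighted_quantile(x, w, [0.25, 0.5, 0.75])
        out[f"mean_{label}"] = mean
        out[f"sd_{label}"] = sd
        out[f"median_{label}"] = float(q50)
        out[f"iqr_low_{label}"] = float(q25)
        out[f"iqr_high_{label}"] = float(q75)

    for payer, grp in records.groupby("payer"):
        out[f"share_{payer}"] = float(grp["weight"].sum() / total)
    for col, d in zip(DIAGNOSIS_COLUMNS, DIAGNOSES):
        out[f"prevalence_{d}"] = float(
            np.average(records[col].to_numpy(float), weights=w)
        )
    if "food_insecure" in records.columns:
        out["prevalence_food_insecure"] = float(
            np.average(records["food_insecure"].to_numpy(float), weights=w)
        )
    return pd.Series(out)


def stratum_totals(records: pd.DataFrame) -> pd.DataFrame:
    """Per-payer weighted totals used by the simulation engine.

    Columns: ``weight`` (persons), ``hospitalizations`` (weighted annual
    count), ``expenditures`` (weighted annual USD).
    """
    g = records.assign(
        _wh=records["weight"] * records["annual_hospitalizations"],
        _we=records["weight"] * records["annual_expenditure"],
    ).groupby("payer")
    return pd.DataFrame(
        {
            "weight": g["weight"].sum(),
            "hospitalizations": g["_wh"].sum(),
            "expenditures": g["_we"].sum(),
        }
    )
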