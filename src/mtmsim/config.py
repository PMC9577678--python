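"""YAML/JSON model configuration: loading, strict validation, defaults.

A configuration has four blocks — ``population``, ``effects``, ``costs``,
``engine`` — all optional; omitted values resolve to the calibrated package
defaults.  Validation is strict: unknown keys raise, and constraint
violations name the offending key path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import defaults
from .costs import CostInputs
from .pooling import PooledEffect
from .population import DIAGNOSES, PopulationSpec, StratumSpec


class ConfigError(ValueError):
    """Configuration file is malformed, has unknown keys, or violates a bound."""


_EFFECT_KEYS = {"estimate", "ci_low", "ci_high"}
_COST_KEYS = {
    "screening_cost_low",
    "screening_cost_high",
    "monthly_meal_cost_mean",
    "monthly_meal_cost_sd",
    "months_of_meals",
    "per_meal_cost_mean",
    "per_meal_cost_sd",
}
_ENGINE_KEYS = {
    "n_replicates",
    "n_records",
    "seed",
    "coverage_fraction",
    "discount_rate",
    "horizon_years",
    "carryover_fraction",
}
_STRATUM_KEYS = {
    "n_population",
    "mean_expenditure",
    "sd_expenditure",
    "mean_hospitalizations",
    "sd_hospitalizations",
    "pop_growth_rate",
    "per_capita_expenditure_growth_rate",
}
_POPULATION_KEYS = {
    "name",
    "base_year",
    "strata",
    "diagnosis_prevalences",
    "food_insecurity_prevalence",
    "expenditure_distribution",
    "hospitalization_distribution",
    "utilization_correlation",
    "deflator",
}
_TOP_KEYS = {"population", "effects", "costs", "engine"}

_DEFAULT_ENGINE = {
    "n_replicates": 1000,
    "n_records": 50_000,
    "seed": 0,
    "coverage_fraction": 1.0,
    "discount_rate": 0.03,
    "horizon_years": 10,
    "carryover_fraction": 0.0,
}


@dataclass(frozen=True)
class ModelConfig:
    """Fully resolved model configuration."""

    population: PopulationSpec
    effects: dict[str, PooledEffect]
    costs: CostInputs
    engine: dict[str, Any]
    raw: dict[str, Any] = field(default_factory=dict, repr=False)


def _check_keys(block: Mapping[str, Any], allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {path!r}")


def _build_population(block: Mapping[str, Any]) -> PopulationSpec:
    _check_keys(block, _POPULATION_KEYS, "population")
    name = block.get("name", "primary_2019")
    if "strata" not in block:
        spec = defaults.population_spec(name)
    else:
        strata = []
        for payer, sdict in block["strata"].items():
            _check_keys(sdict, _STRATUM_KEYS, f"population.strata.{payer}")
            try:
                strata.append(StratumSpec(payer=payer, **sdict))
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"population.strata.{payer}: {exc}") from exc
        prevalences = block.get("diagnosis_prevalences", {})
        _check_keys(prevalences, set(DIAGNOSES), "population.diagnosis_prevalences")
        try:
            spec = PopulationSpec(
                strata=tuple(strata),
                diagnosis_prevalences=prevalences,
                food_insecurity_prevalence=block.get("food_insecurity_prevalence", 0.0),
                expenditure_distribution=block.get("expenditure_distribution", "lognormal"),
                hospitalization_distribution=block.get(
                    "hospitalization_distribution", "negative_binomial"
                ),
                utilization_correlation=block.get("utilization_correlation", 0.5),
                base_year=block.get("base_year", 2019),
                name=name,
            )
        except ValueError as exc:
            raise ConfigError(f"population: {exc}") from exc
    deflator = block.get("deflator", 1.0)
    if deflator <= 0:
        raise ConfigError("population.deflator must be > 0")
    if deflator != 1.0:
        spec = spec.scaled({}, {s.payer: deflator for s in spec.strata})
    return spec


def _build_effects(block: Mapping[str, Any]) -> dict[str, PooledEffect]:
    _check_keys(block, {"expenditure_reduction", "hospitalization_reduction"}, "effects")
    out = {
        "expenditure": defaults.EXPENDITURE_REDUCTION,
        "hospitalization": defaults.HOSPITALIZATION_REDUCTION,
    }
    mapping = {
        "expenditure_reduction": ("expenditure", "expenditure_pct_change"),
        "hospitalization_reduction": ("hospitalization", "hospitalization_rr"),
    }
    for key, (slot, outcome) in mapping.items():
        if key in block:
            _check_keys(block[key], _EFFECT_KEYS, f"effects.{key}")
            try:
                out[slot] = PooledEffect(
                    outcome=outcome, scale="percent_reduction", **block[key]
                )
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"effects.{key}: {exc}") from exc
    return out


def _build_costs(block: Mapping[str, Any]) -> CostInputs:
    _check_keys(block, _COST_KEYS, "costs")
    base = defaults.DEFAULT_COST_INPUTS
    merged = {k: block.get(k, getattr(base, k)) for k in _COST_KEYS}
    try:
        return CostInputs(**merged)
    except ValueError as exc:
        raise ConfigError(f"costs: {exc}") from exc


def _build_engine(block: Mapping[str, Any]) -> dict[str, Any]:
    _check_keys(block, _ENGINE_KEYS, "engine")
    engine = {**_DEFAULT_ENGINE, **block}
    if not 0.0 <= engine["coverage_fraction"] <= 1.0:
        raise ConfigError("engine.coverage_fraction must lie in [0, 1]")
    if engine["discount_rate"] < 0:
        raise ConfigError("engine.discount_rate must be >= 0")
    if not 0.0 <= engine["carryover_fraction"] <= 1.0:
        raise ConfigError("engine.carryover_fraction must lie in [0, 1]")
    if engine["n_replicates"] < 1:
        raise ConfigError("engine.n_replicates must be >= 1")
    if engine["horizon_years"] < 1:
        raise ConfigError("engine.horizon_years must be >= 1")
    return engine


def resolve_config(data: Mapping[str, Any]) -> ModelConfig:
    """Validate a raw config mapping and resolve all defaults."""
    data = dict(data or {})
    _check_keys(data, _TOP_KEYS, "<top level>")
    return ModelConfig(
        population=_build_population(data.get("population", {}) or {}),
        effects=_build_effects(data.get("effects", {}) or {}),
        costs=_build_costs(data.get("costs", {}) or {}),
        engine=_build_engine(data.get("engine", {}) or {}),
        raw=data,
    )


def load_config(source: str | Path | None = None) -> ModelConfig:
    """Load and validate a config from a YAML/JSON path or a shipped name.

    ``source`` may be a file path, one of the shipped config names
    (``primary_2019``, ``food_insecure_2017``, ``diabetes_only``,
    ``chf_only``), or ``None`` for the full default configuration.
    """
    if source is None:
        return resolve_config({})
    if isinstance(source, str) and source in defaults.POPULATION_NAMES:
        text = (
            resources.files("mtmsim") / "data" / f"{source}.yaml"
        ).read_text(encoding="utf-8")
        return resolve_config(yaml.safe_load(text))
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return resolve_config(data)


def dump_config(config: ModelConfig | Mapping[str, Any], path: str | Path) -> None:
    """Write the raw (unresolved) config mapping back to YAML or JSON."""
    raw = config.raw if isinstance(config, ModelConfig) else dict(config)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(raw, indent=2, sort_keys=True), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=True), encoding="utf-8")
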