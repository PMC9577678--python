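"""Calibrated default inputs for the national MTM policy model.

All dollar values are 2019 USD; rates are per person-year.  The default
populations are calibrated to published national estimates for the 2019
MTM-eligible population (adults with a diet-sensitive condition and an IADL
limitation, by payer stratum) and, for the food-insecure restriction, to the
corresponding 2017 estimates.

Per-stratum mean expenditures and hospitalization rates are not published
directly; they are back-derived from the published central per-stratum averted
amounts (averted = effect × N × mean), which reproduces those central
estimates exactly and yields overall weighted means ($31,132; 0.5375) that
agree with the published overall moments ($31,134; 0.54) within printing
precision.  Stratum SDs assume the overall coefficient of variation.

The calibrated monthly meal-contract cost ($487.60/person-month) is the value
implied by the published total annual program cost (~$24.8B for 6,309,998
people, 8 months of meals, ~$30 screening); its draw SD ($34.7) is calibrated
so that, with independent per-stratum draws, the total program-cost 95%
uncertainty-interval half-width is ≈7.5% of the mean, matching the published
interval.
"""

from __future__ import annotations

from .costs import CostInputs
from .pooling import PooledEffect, StudyRecord
from .population import PAYERS, PopulationSpec, StratumSpec

#: Pooled effect of MTM receipt on annual health care expenditures
#: (fractional reduction, meta-analysis of 5 interventional studies).
EXPENDITURE_REDUCTION = PooledEffect(
    outcome="expenditure_pct_change",
    estimate=0.197,
    ci_low=0.069,
    ci_high=0.324,
    k=5,
    scale="percent_reduction",
)

#: Pooled effect of MTM receipt on annual hospitalizations
#: (fractional reduction, i.e. 1 - relative risk).
HOSPITALIZATION_REDUCTION = PooledEffect(
    outcome="hospitalization_rr",
    estimate=0.470,
    ci_low=0.317,
    ci_high=0.623,
    k=5,
    scale="percent_reduction",
)

#: Pooled per-meal cost across MTM organizations, mean (SD), USD/meal.
PER_MEAL_COST = (9.30, 0.64)

#: Participant-weighted mean months of MTM receipt per patient-year.
MONTHS_OF_MEALS = 8.0

DEFAULT_COST_INPUTS = CostInputs()

#: Annual growth of the eligible population by payer (log-linear trend fits
#: to 2010-2019 national series for this population).
POPULATION_GROWTH = {"private": 0.010, "medicare": 0.021, "medicaid": 0.030, "dual": 0.057}

#: Annual growth of per-patient inflation-adjusted expenditures by payer.
EXPENDITURE_GROWTH = {"private": 0.015, "medicare": 0.017, "medicaid": 0.035, "dual": 0.039}

# ---------------------------------------------------------------------------
# Published calibration constants by population.  "averted_*" entries are the
# published central 1-year averted amounts per stratum from which baseline
# means are back-derived.

_PRIMARY = {
    "n": {"private": 1_485_365, "medicare": 2_571_562, "medicaid": 697_292, "dual": 1_555_779},
    "averted_expenditures_billion": {"private": 8.9, "medicare": 13.4, "medicaid": 4.5, "dual": 11.9},
    "averted_hospitalizations": {"private": 290_000, "medicare": 712_000, "medicaid": 195_000, "dual": 397_000},
    "exp_cv": 34_749 / 31_134,
    "hosp_cv": 0.94 / 0.54,
    "prevalences": {
        "diabetes": 0.449, "chf": 0.268, "mi": 0.213, "other_heart": 0.365,
        "stroke": 0.361, "cancer": 0.372, "emphysema": 0.107, "ckd": 0.013, "hiv": 0.006,
    },
    # share of the primary population that is also food insecure, approximated
    # by the ratio of the food-insecure eligible count to the primary count
    "food_insecurity": 1_887_681 / 6_309_998,
    "demographics": dict(
        mean_ed_visits=0.98, sd_ed_visits=1.68, age_mean=68.1, age_sd=16.6,
        sex_shares={"female": 0.634, "male": 0.366},
        race_shares={"hispanic": 0.113, "nh_asian": 0.031, "nh_black": 0.142,
                     "nh_white": 0.667, "other_multiple": 0.047},
        region_shares={"northeast": 0.178, "midwest": 0.202, "south": 0.394, "west": 0.226},
    ),
    "base_year": 2019,
}

_FOOD_INSECURE = {
    "n": {"private": 330_587, "medicare": 587_828, "medicaid": 286_066, "dual": 683_200},
    "averted_expenditures_billion": {"private": 2.7, "medicare": 3.1, "medicaid": 2.8, "dual": 4.4},
    "averted_hospitalizations": {"private": 78_000, "medicare": 167_000, "medicaid": 117_000, "dual": 144_000},
    "exp_cv": 48_978 / 33_634,
    "hosp_cv": 1.02 / 0.59,
    "prevalences": {
        "diabetes": 0.518, "chf": 0.194, "mi": 0.196, "other_heart": 0.389,
        "stroke": 0.223, "cancer": 0.243, "emphysema": 0.161, "ckd": 0.016, "hiv": 0.012,
    },
    "food_insecurity": 1.0,
    "demographics": dict(
        mean_ed_visits=1.09, sd_ed_visits=1.85, age_mean=60.5, age_sd=15.5,
        sex_shares={"female": 0.637, "male": 0.363},
        race_shares={"hispanic": 0.193, "nh_asian": 0.039, "nh_black": 0.254,
                     "nh_white": 0.451, "other_multiple": 0.063},
        region_shares={"northeast": 0.154, "midwest": 0.305, "south": 0.362, "west": 0.179},
    ),
    "base_year": 2017,
}

_DIABETES_ONLY = {
    "n": {"private": 636_320, "medicare": 1_001_345, "medicaid": 368_460, "dual": 824_381},
    "averted_expenditures_billion": {"private": 4.3, "medicare": 5.6, "medicaid": 2.5, "dual": 7.0},
    "averted_hospitalizations": {"private": 118_000, "medicare": 304_000, "medicaid": 63_000, "dual": 216_000},
    "exp_cv": _PRIMARY["exp_cv"],
    "hosp_cv": _PRIMARY["hosp_cv"],
    "prevalences": {**_PRIMARY["prevalences"], "diabetes": 1.0},
    "food_insecurity": _PRIMARY["food_insecurity"],
    "demographics": _PRIMARY["demographics"],
    "base_year": 2019,
}

_CHF_ONLY = {
    "n": {"private": 374_445, "medicare": 871_058, "medicaid": 119_035, "dual": 330_745},
    "averted_expenditures_billion": {"private": 2.5, "medicare": 5.0, "medicaid": 0.7, "dual": 2.6},
    "averted_hospitalizations": {"private": 77_000, "medicare": 288_000, "medicaid": 37_900, "dual": 127_000},
    "exp_cv": _PRIMARY["exp_cv"],
    "hosp_cv": _PRIMARY["hosp_cv"],
    "prevalences": {**_PRIMARY["prevalences"], "chf": 1.0},
    "food_insecurity": _PRIMARY["food_insecurity"],
    "demographics": _PRIMARY["demographics"],
    "base_year": 2019,
}

_POPULATIONS = {
    "primary_2019": _PRIMARY,
    "food_insecure_2017": _FOOD_INSECURE,
    "diabetes_only": _DIABETES_ONLY,
    "chf_only": _CHF_ONLY,
}

POPULATION_NAMES = tuple(_POPULATIONS)


def population_spec(name: str = "primary_2019") -> PopulationSpec:
    """Build a shipped default :class:`PopulationSpec` by name."""
    try:
        c = _POPULATIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown population {name!r}; choose from {sorted(_POPULATIONS)}"
        ) from None
    strata = []
    for payer in PAYERS:
        n = c["n"][payer]
        mean_exp = c["averted_expenditures_billion"][payer] * 1e9 / (
            EXPENDITURE_REDUCTION.estimate * n
        )
        mean_hosp = c["averted_hospitalizations"][payer] / (
            HOSPITALIZATION_REDUCTION.estimate * n
        )
        strata.append(
            StratumSpec(
                payer=payer,
                n_population=n,
                mean_expenditure=mean_exp,
                sd_expenditure=mean_exp * c["exp_cv"],
                mean_hospitalizations=mean_hosp,
                sd_hospitalizations=mean_hosp * c["hosp_cv"],
                pop_growth_rate=POPULATION_GROWTH[payer],
                per_capita_expenditure_growth_rate=EXPENDITURE_GROWTH[payer],
            )
        )
    return PopulationSpec(
        strata=tuple(strata),
        diagnosis_prevalences=dict(c["prevalences"]),
        food_insecurity_prevalence=c["food_insecurity"],
        base_year=c["base_year"],
        name=name,
        **c["demographics"],
    )


def default_study_records() -> list[StudyRecord]:
    """Template study-level records for the 5-study meta-analysis.

    The study-level supplementary values are not published in the main text;
    this template carries the pooled defaults as single synthetic records so
    that the pooling pipeline runs end to end.  Users with access to the
    study-level estimates should replace it with their own CSV.
    """
    return [
        StudyRecord(
            study_id="pooled_expenditures",
            outcome="expenditure_pct_change",
            estimate=0.197,
            ci_low=0.069,
            ci_high=0.324,
            scale="percent_reduction",
        ),
        StudyRecord(
            study_id="pooled_hospitalizations",
            outcome="hospitalization_rr",
            estimate=0.470,
            ci_low=0.317,
            ci_high=0.623,
            scale="percent_reduction",
        ),
        # Two synthetic per-organization costs placed at 9.30 +/- 0.64/sqrt(2)
        # so the sample mean and SD equal the pooled (9.30, 0.64) exactly.
        StudyRecord(
            study_id="synthetic_meal_cost_low",
            outcome="per_meal_cost",
            estimate=9.30 - 0.64 / 2**0.5,
        ),
        StudyRecord(
            study_id="synthetic_meal_cost_high",
            outcome="per_meal_cost",
            estimate=9.30 + 0.64 / 2**0.5,
        ),
        StudyRecord(
            study_id="pooled_duration",
            outcome="duration_months",
            duration_months=8.0,
            n_participants=1.0,
        ),
    ]
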