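"""Synthetic-population generator: calibration, eligibility, round-trip I/O."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mtmsim as m
from mtmsim.population import (
    DIAGNOSIS_COLUMNS,
    SchemaError,
    lognormal_median,
    population_summary,
)


class TestGeneration:
    def test_empty_generation(self, tiny_spec):
        table = m.generate_population(tiny_spec, 0, seed=1)
        assert len(table) == 0
        assert table["weight"].sum() == 0.0

    def test_same_seed_is_byte_identical(self, tiny_spec):
        a = m.generate_population(tiny_spec, 500, seed=7)
        b = m.generate_population(tiny_spec, 500, seed=7)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = m.generate_population(tiny_spec, 500, seed=8)
        assert not a["annual_expenditure"].equals(c["annual_expenditure"])

    def test_weight_conservation_is_exact(self, tiny_spec):
        for n in (10, 999, 2_000):
            table = m.generate_population(tiny_spec, n, seed=3)
            for s in tiny_spec.strata:
                got = table.loc[table["payer"] == s.payer, "weight"].sum()
                assert got == pytest.approx(s.n_population, rel=1e-12)

    def test_every_record_is_eligible_by_construction(self, tiny_records):
        assert tiny_records["iadl_limited"].all()
        assert tiny_records[list(DIAGNOSIS_COLUMNS)].any(axis=1).all()

    def test_calibrated_moments_within_three_se(self, default_config, primary_records):
        """Weighted sample moments converge to the calibration targets.

        At n = 50,000 every calibrated weighted moment must lie within three
        standard errors of its target (overall means, stratum shares, and the
        diabetes prevalence near its published 44.9%).
        """
        spec = default_config.population
        summ = population_summary(primary_records)
        n = len(primary_records)
        total = spec.total_population

        target_mean_exp = sum(s.n_population * s.mean_expenditure for s in spec.strata) / total
        target_sd_exp = np.sqrt(
            sum(s.n_population * (s.sd_expenditure**2 + s.mean_expenditure**2) for s in spec.strata) / total
            - target_mean_exp**2
        )
        se_exp = target_sd_exp / np.sqrt(n)
        assert abs(summ["mean_expenditure"] - target_mean_exp) < 3 * se_exp
        # published overall mean is indistinguishable from the stratum-derived one
        assert abs(summ["mean_expenditure"] - 31_134) < 3 * se_exp

        target_mean_hosp = sum(
            s.n_population * s.mean_hospitalizations for s in spec.strata
        ) / total
        target_sd_hosp = target_mean_hosp * (0.94 / 0.54)
        se_hosp = target_sd_hosp / np.sqrt(n)
        assert abs(summ["mean_hospitalizations"] - target_mean_hosp) < 3 * se_hosp
        assert abs(summ["mean_hospitalizations"] - 0.54) < 3 * se_hosp

        p = 0.449
        se_p = np.sqrt(p * (1 - p) / n)
        assert abs(summ["prevalence_diabetes"] - p) < 3 * se_p

        for s in spec.strata:
            assert summ[f"share_{s.payer}"] == pytest.approx(s.n_population / total, rel=5e-3)

    def test_lognormal_family_reproduces_printed_median(self):
        """Moment-matched lognormal (mean 31,134, SD 34,749) implies a median
        near the published $20,107 (within 5%); oracle is the closed form
        median = mean / sqrt(1 + CV^2)."""
        mean, sd = 31_134.0, 34_749.0
        med = lognormal_median(mean, sd)
        assert med == pytest.approx(mean / np.sqrt(1 + (sd / mean) ** 2), rel=1e-12)
        assert med == pytest.approx(20_775, abs=5.0)
        assert abs(med - 20_107) / 20_107 < 0.05

    def test_expenditure_hospitalization_rank_correlation_positive(self, default_config):
        spec = default_config.population
        table = m.generate_population(spec, 20_000, seed=5)
        rho = (
            table[["annual_expenditure", "annual_hospitalizations"]]
            .corr(method="spearman")
            .iloc[0, 1]
        )
        assert rho > 0.2

    def test_invalid_spec_names_offending_field(self):
        with pytest.raises(ValueError, match="sd_expenditure"):
            m.StratumSpec("private", 1000, 20_000, -1.0, 0.5, 0.9)
        with pytest.raises(ValueError, match="n_population"):
            m.StratumSpec("private", 0, 20_000, 1.0, 0.5, 0.9)
        with pytest.raises(ValueError, match="food_insecurity_prevalence"):
            m.PopulationSpec(
                strata=(m.StratumSpec("private", 1000, 20_000, 1.0, 0.5, 0.9),),
                diagnosis_prevalences={"diabetes": 0.5},
                food_insecurity_prevalence=1.5,
            )

    def test_gamma_family_matches_target_moments(self, tiny_spec):
        from dataclasses import replace

        spec = replace(tiny_spec, expenditure_distribution="gamma")
        table = m.generate_population(spec, 30_000, seed=9)
        summ = population_summary(table)
        target = sum(
            s.n_population * s.mean_expenditure for s in spec.strata
        ) / spec.total_population
        assert summ["mean_expenditure"] == pytest.approx(target, rel=0.02)


class TestEligibility:
    PRIMARY = m.EligibilityCriteria(
        required_diagnoses=frozenset(m.DIAGNOSES), require_iadl=True
    )

    def test_primary_criteria_enumeration(self, toy_six):
        """Exhaustive 6-record enumeration: diagnosis AND IADL required."""
        kept = m.apply_eligibility_filter(toy_six, self.PRIMARY)
        assert list(kept["person_id"]) == ["a", "b", "f"]
        pd.testing.assert_frame_equal(kept, toy_six.loc[kept.index])  # untouched rows

    def test_food_insecurity_gate(self, toy_six):
        crit = m.EligibilityCriteria(
            required_diagnoses=frozenset(m.DIAGNOSES),
            require_iadl=True,
            require_food_insecurity=True,
        )
        kept = m.apply_eligibility_filter(toy_six, crit)
        assert list(kept["person_id"]) == ["f"]

    def test_single_diagnosis_criteria(self, toy_six):
        crit = m.EligibilityCriteria(required_diagnoses=frozenset({"chf"}))
        assert list(m.apply_eligibility_filter(toy_six, crit)["person_id"]) == ["f"]

    def test_empty_input_and_idempotence(self, toy_six):
        empty = toy_six.iloc[0:0]
        assert m.apply_eligibility_filter(empty, self.PRIMARY).empty
        once = m.apply_eligibility_filter(toy_six, self.PRIMARY)
        twice = m.apply_eligibility_filter(once, self.PRIMARY)
        pd.testing.assert_frame_equal(once, twice)

    def test_criteria_require_nonempty_diagnoses(self):
        with pytest.raises(ValueError):
            m.EligibilityCriteria(required_diagnoses=frozenset())


class TestPersonTableIO:
    def test_round_trip_identity(self, toy_six, tmp_path):
        path = tmp_path / "toy.csv"
        m.write_person_table(toy_six, path)
        back = m.read_person_table(path)
        pd.testing.assert_frame_equal(back, toy_six, check_dtype=False)
        assert back["iadl_limited"].dtype == bool
        assert back["dx_diabetes"].dtype == bool

    def test_round_trip_on_generated_table(self, tiny_records, tmp_path):
        path = tmp_path / "gen.csv"
        m.write_person_table(tiny_records, path)
        back = m.read_person_table(path)
        pd.testing.assert_frame_equal(back, tiny_records, check_dtype=False)

    def test_missing_mandatory_column_is_named(self, toy_six, tmp_path):
        path = tmp_path / "bad.csv"
        m.write_person_table(toy_six.drop(columns=["weight"]), path)
        with pytest.raises(SchemaError, match="weight"):
            m.read_person_table(path)

    def test_non_numeric_weight_reports_row(self, toy_six, tmp_path):
        path = tmp_path / "bad.csv"
        broken = toy_six.copy()
        broken["weight"] = broken["weight"].astype(object)
        broken.loc[2, "weight"] = "heavy"
        m.write_person_table(broken, path)
        with pytest.raises(SchemaError, match=r"weight.*row 2"):
            m.read_person_table(path)

    def test_unknown_column_warns_and_drops(self, toy_six, tmp_path, caplog):
        path = tmp_path / "extra.csv"
        m.write_person_table(toy_six.assign(favorite_color="blue"), path)
        with caplog.at_level("WARNING", logger="mtmsim.population"):
            back = m.read_person_table(path)
        assert "favorite_color" in caplog.text
        assert "favorite_color" not in back.columns


class TestSummary:
    def test_unit_weights_match_hand_arithmetic(self, toy_six):
        summ = population_summary(toy_six)
        assert summ["weighted_n"] == 6
        assert summ["mean_expenditure"] == pytest.approx(10_000.0)
        assert summ["prevalence_diabetes"] == pytest.approx(3 / 6)
        assert summ["prevalence_chf"] == pytest.approx(1 / 6)

    def test_single_record_weight_ten(self, toy_six):
        one = toy_six.iloc[[0]].assign(weight=10.0)
        summ = population_summary(one)
        assert summ["weighted_n"] == 10
        assert summ["mean_expenditure"] == pytest.approx(10_000.0)
        assert summ["sd_expenditure"] == 0.0
        assert summ["median_expenditure"] == pytest.approx(10_000.0)

    def test_empty_population_errors(self, toy_six):
        with pytest.raises(ValueError, match="non-empty"):
            population_summary(toy_six.iloc[0:0])
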