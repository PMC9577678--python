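"""One-year Monte Carlo engine: draw distributions, accounting identities,
coverage linearity, reproducibility, and convergence to closed form."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mtmsim as m
from mtmsim.engine import summarize_simulations, truncated_normal


def pct(frame, col, q):
    return np.percentile(frame[col].to_numpy(), q)


class TestDrawEffects:
    def test_degenerate_draws_equal_central_estimates(self, degenerate_effects):
        rng = np.random.default_rng(0)
        draws = m.draw_effects(
            degenerate_effects["expenditure"], degenerate_effects["hospitalization"], rng
        )
        assert draws.expenditure_reduction == 0.197
        assert draws.hospitalization_reduction == 0.470

    def test_draw_percentiles_recover_pooled_ci(self, default_config):
        exp = default_config.effects["expenditure"]
        rng = np.random.default_rng(1)
        draws = truncated_normal(exp.estimate, exp.se, 0.0, 1.0, rng, 10_000)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        assert lo == pytest.approx(0.069, abs=0.005)
        assert hi == pytest.approx(0.324, abs=0.005)

    def test_truncation_forbids_negative_draws(self):
        rng = np.random.default_rng(2)
        draws = truncated_normal(0.02, 0.05, 0.0, 1.0, rng, 20_000)
        assert draws.min() >= 0.0
        assert draws.max() <= 1.0

    def test_effect_draw_bounds_validated(self):
        with pytest.raises(ValueError, match="expenditure_reduction"):
            m.EffectDraws(expenditure_reduction=1.2, hospitalization_reduction=0.5)


class TestSimulateReplicate:
    def test_zero_effects_leave_only_costs(self, tiny_records):
        effects = m.EffectDraws(0.0, 0.0)
        draw = m.CostDraw(screening_cost=30.0, monthly_meal_cost=500.0)
        frame = m.simulate_replicate(tiny_records, effects, draw, 1.0, 8.0)
        assert (frame["averted_hospitalizations"] == 0).all()
        assert (frame["averted_expenditures"] == 0).all()
        assert np.allclose(frame["net_savings"], -frame["program_cost"])

    def test_hand_computed_totals_on_toy_table(self, toy_six):
        effects = m.EffectDraws(0.2, 0.5)
        draw = m.CostDraw(screening_cost=10.0, monthly_meal_cost=100.0)
        table = toy_six.assign(
            annual_hospitalizations=[1, 2, 0, 3, 1, 2], weight=2.0
        )
        frame = m.simulate_replicate(table, effects, draw, 1.0, 8.0)
        # independent arithmetic: weighted hosp = 2*9 = 18; exp = 2*6*10000
        assert frame.loc["total", "averted_hospitalizations"] == pytest.approx(0.5 * 18)
        assert frame.loc["total", "averted_expenditures"] == pytest.approx(0.2 * 120_000)
        assert frame.loc["total", "program_cost"] == pytest.approx(12 * (8 * 100 + 10))
        assert frame.loc["total", "net_savings"] == pytest.approx(
            0.2 * 120_000 - 12 * 810
        )

    def test_coverage_bounds(self, tiny_records):
        with pytest.raises(ValueError, match="coverage_fraction"):
            m.simulate_replicate(
                tiny_records, m.EffectDraws(0.1, 0.1),
                m.CostDraw(30.0, 500.0), coverage_fraction=1.5,
            )


class TestRunMonteCarlo:
    def test_degenerate_inputs_collapse_uncertainty(
        self, tiny_records, degenerate_effects, degenerate_costs
    ):
        res = m.run_monte_carlo(
            tiny_records, degenerate_effects, degenerate_costs,
            n_replicates=50, seed=0, bootstrap=False,
        )
        for q in ("averted_hospitalizations", "averted_expenditures", "program_cost", "net_savings"):
            lo = res.summary[f"{q}_ui_low"]
            hi = res.summary[f"{q}_ui_high"]
            mean = res.summary[f"{q}_mean"]
            assert np.allclose(lo, mean) and np.allclose(hi, mean)

    def test_accounting_identity_every_replicate(self, primary_mc):
        reps = primary_mc.replicates
        assert np.allclose(
            reps["net_savings"],
            reps["averted_expenditures"] - reps["program_cost"],
            rtol=0, atol=1e-6,
        )

    def test_stratum_additivity_every_replicate(self, primary_mc):
        reps = primary_mc.replicates
        strata = reps[reps["stratum"] != "total"]
        total = reps[reps["stratum"] == "total"].set_index("replicate")
        summed = strata.groupby("replicate")[
            ["averted_hospitalizations", "averted_expenditures", "program_cost", "net_savings"]
        ].sum()
        assert np.allclose(summed, total[summed.columns], rtol=1e-12)

    def test_coverage_linearity_replicate_wise(self, primary_mc, coverage50_mc):
        full = primary_mc.replicates.set_index(["stratum", "replicate"]).sort_index()
        half = coverage50_mc.replicates.set_index(["stratum", "replicate"]).sort_index()
        for q in ("averted_hospitalizations", "averted_expenditures", "program_cost"):
            assert np.array_equal(2.0 * half[q].to_numpy(), full[q].to_numpy())

    def test_reproducibility_bit_identical(self, tiny_records, default_config):
        kwargs = dict(n_replicates=40, seed=123)
        a = m.run_monte_carlo(tiny_records, default_config.effects, default_config.costs, **kwargs)
        b = m.run_monte_carlo(tiny_records, default_config.effects, default_config.costs, **kwargs)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        pd.testing.assert_frame_equal(a.summary, b.summary)
        assert a.fraction_cost_saving == b.fraction_cost_saving

    def test_mc_mean_converges_to_closed_form(
        self, tiny_spec, tiny_records, degenerate_costs, default_config
    ):
        """Replicate mean matches the spec-level point estimate within 2 MC SEs."""
        res = m.run_monte_carlo(
            tiny_records, default_config.effects, degenerate_costs,
            n_replicates=800, seed=7,
        )
        reps = res.replicates
        total = reps[reps["stratum"] == "total"]["averted_expenditures"]
        mc_se = total.std(ddof=1) / np.sqrt(len(total))
        point = m.central_value_from_spec(
            tiny_spec, default_config.effects, degenerate_costs
        ).loc["total", "averted_expenditures"]
        # sampled baseline differs from spec targets by <~1.5 SE of the sample mean
        sampling_tol = 3 * point / np.sqrt(len(tiny_records))
        assert abs(total.mean() - point) < 2 * mc_se + sampling_tol

    def test_effect_monotonicity_holding_draws_fixed(self, tiny_records):
        draw = m.CostDraw(30.0, 500.0)
        lo = m.simulate_replicate(tiny_records, m.EffectDraws(0.1, 0.2), draw)
        hi = m.simulate_replicate(tiny_records, m.EffectDraws(0.3, 0.6), draw)
        assert (hi["averted_expenditures"] >= lo["averted_expenditures"]).all()
        assert (hi["averted_hospitalizations"] >= lo["averted_hospitalizations"]).all()
        dearer = m.CostDraw(30.0, 900.0)
        cheap = m.simulate_replicate(tiny_records, m.EffectDraws(0.2, 0.4), draw)
        costly = m.simulate_replicate(tiny_records, m.EffectDraws(0.2, 0.4), dearer)
        assert (costly["net_savings"] <= cheap["net_savings"]).all()

    def test_domain_errors(self, tiny_records, default_config):
        with pytest.raises(ValueError, match="n_replicates"):
            m.run_monte_carlo(tiny_records, default_config.effects, default_config.costs, n_replicates=0)
        with pytest.raises(ValueError, match="coverage_fraction"):
            m.run_monte_carlo(
                tiny_records, default_config.effects, default_config.costs,
                n_replicates=2, coverage_fraction=-0.1,
            )


class TestSummarize:
    def test_constant_replicates(self):
        reps = pd.DataFrame(
            {
                "replicate": range(10),
                "stratum": "total",
                "averted_hospitalizations": 5.0,
                "averted_expenditures": 7.0,
                "program_cost": 2.0,
                "net_savings": 5.0,
            }
        )
        summ = summarize_simulations(reps)
        row = summ.loc["total"]
        assert row["averted_expenditures_mean"] == 7.0
        assert row["averted_expenditures_ui_low"] == 7.0
        assert row["averted_expenditures_ui_high"] == 7.0

    def test_known_quantiles_and_mean(self):
        rng = np.random.default_rng(5)
        normals = rng.standard_normal(100_000)
        reps = pd.DataFrame(
            {
                "replicate": range(100_000),
                "stratum": "total",
                "averted_hospitalizations": normals,
                "averted_expenditures": np.arange(1.0, 100_001.0),
                "program_cost": 0.0,
                "net_savings": 0.0,
            }
        )
        summ = summarize_simulations(reps)
        assert summ.loc["total", "averted_hospitalizations_ui_low"] == pytest.approx(-1.96, abs=0.05)
        assert summ.loc["total", "averted_hospitalizations_ui_high"] == pytest.approx(1.96, abs=0.05)
        assert summ.loc["total", "averted_expenditures_mean"] == pytest.approx(50_000.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_simulations(pd.DataFrame(columns=["stratum"]))
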