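#!/usr/bin/env python
"""Ten-year open-cohort projection (2019-2028) with alternative discounting.

Projects the primary population forward at the fitted stratum growth rates
(population 1.0/2.1/3.0/5.7%/yr; per-capita expenditures 1.5/1.7/3.5/3.9%/yr
for private/Medicare/Medicaid/dual), sums yearly 1000-replicate simulations
at 0%, 3%, and 5% discounting, and adds the 15%-carryover sensitivity run.
Cumulative tables land under results/ten_year/.
"""

from pathlib import Path

import pandas as pd

import mtmsim as m

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "ten_year"
SEED = 2019
N_RECORDS = 50_000
N_REPLICATES = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = m.load_config()
    records = m.generate_population(cfg.population, N_RECORDS, seed=SEED)
    growth = m.growth_models_from_spec(cfg.population)

    rows = []
    for label, rate, carry in (
        ("no_discounting", 0.0, 0.0),
        ("discount_3pct", 0.03, 0.0),
        ("discount_5pct", 0.05, 0.0),
        ("discount_3pct_carryover_15pct", 0.03, 0.15),
    ):
        result = m.simulate_multi_year(
            records, growth, cfg.effects, cfg.costs,
            years=10, discount_rate=rate, carryover_fraction=carry,
            n_replicates=N_REPLICATES, seed=SEED + 2,
        )
        m.save_result(result, OUT, prefix=label)
        rows.append(
            {
                "scenario": label,
                "averted_hospitalizations_mean": result.total("averted_hospitalizations"),
                "averted_expenditures_billion": result.total("averted_expenditures") / 1e9,
                "program_cost_billion": result.total("program_cost") / 1e9,
                "net_savings_billion": result.total("net_savings") / 1e9,
            }
        )
        print(
            f"{label}: {result.total('averted_hospitalizations') / 1e6:.2f}M averted "
            f"hospitalizations; ${result.total('net_savings') / 1e9:.1f}B cumulative "
            f"net savings"
        )
    table = pd.DataFrame(rows).set_index("scenario")
    table.to_csv(OUT / "ten_year_overview.csv")
    print(
        "\nHospitalization totals are identical across discount rates "
        "(counts are never discounted); dollar totals fall as the rate rises."
    )
    print(f"Outputs in {OUT}")


if __name__ == "__main__":
    main()
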