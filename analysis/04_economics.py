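#!/usr/bin/env python
"""Monetize the averted burden: VSL for averted deaths (headline
NCD+LRI category), cost-of-illness for averted admissions, discounted
at 5%/yr to 2020.

Reads the burden tables from results/ (run 03 first); writes
results/economics.csv and prints national annual-average benefits per
scenario with the per-capita value.
"""

from pathlib import Path

import pandas as pd

from pm25hia import demography
from pm25hia.burden_engine import averted_events
from pm25hia.economics import EconomicParams, benefits_table
from pm25hia.io_cli import read_table, write_table

OUT = Path("results")


def main() -> None:
    cities = read_table(OUT / "panel/cities.csv", "cities")
    agg = pd.read_csv(OUT / "burden_all.csv")
    costs = demography.project_unit_costs(
        read_table(OUT / "panel/cost_history.csv", "cost_history")
    )
    pop = demography.project_population(
        read_table(OUT / "panel/population.csv", "population"),
        read_table(OUT / "panel/ssp_multipliers.csv", "ssp_multipliers"),
        ssps=["SSP2"],
    )

    base = agg[agg["scenario"] == "baseline"]
    averted = pd.concat(
        [averted_events(base, agg[agg["scenario"] == sc])
         for sc in ("policy", "who15", "who10", "who5")],
        ignore_index=True,
    )
    yearly = averted[~averted["year"].str.contains("-")].assign(
        year=lambda d: d["year"].astype(int)
    )

    pop_period = pop[(pop["year"] >= 2021) & (pop["year"] <= 2030)]
    person_years = {"national": float(pop_period["persons"].sum())}
    by = pop_period.merge(cities[["city_id", "province", "region"]], on="city_id")
    person_years.update(by.groupby("province")["persons"].sum().to_dict())
    person_years.update(by.groupby("region")["persons"].sum().to_dict())

    mort = yearly[yearly["family"] == "gemm"]
    morb = yearly[yearly["family"] == "loglinear"].rename(columns={"cause": "endpoint"})
    econ = benefits_table(
        mort[["scenario", "ssp", "geography", "cause", "year", "averted"]],
        morb[["scenario", "ssp", "geography", "endpoint", "year", "averted"]],
        costs, person_years, EconomicParams(),
    )
    write_table(econ, OUT / "economics.csv")

    nat = econ[econ["geography"] == "national"]
    print("national discounted benefits, annual average 2021-2030 (SSP2):")
    for _, r in nat.iterrows():
        print(f"  {r['scenario']:>9s}: ${r['annual_average_benefit_usd'] / 1e9:6.1f}B/yr "
              f"(mortality ${r['mortality_benefit_usd'] / 10 / 1e9:.1f}B, "
              f"morbidity ${r['morbidity_benefit_usd'] / 10 / 1e6:.0f}M), "
              f"${r['per_capita_usd_per_year']:.1f}/person/yr")


if __name__ == "__main__":
    main()
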