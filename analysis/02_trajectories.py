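#!/usr/bin/env python
"""Build 2020-2030 concentration trajectories for all five scenarios and
confirm the pointwise dominance ordering who5 <= who10 <= who15 <=
policy <= baseline across every city-year.

Reads results/panel/cities.csv (run 01 first); writes
results/trajectories.csv.
"""

from pathlib import Path

from pm25hia.io_cli import read_table, write_table
from pm25hia.scenario_engine import build_trajectories, default_scenarios

OUT = Path("results")


def main() -> None:
    cities = read_table(OUT / "panel/cities.csv", "cities")
    traj = build_trajectories(cities, default_scenarios())
    write_table(traj, OUT / "trajectories.csv")

    wide = traj.pivot_table(index=["city_id", "year"], columns="scenario", values="pm25")
    order = ["who5", "who10", "who15", "policy", "baseline"]
    ok = all(
        (wide[a] <= wide[b] + 1e-9).all() for a, b in zip(order, order[1:])
    )
    print(f"{len(traj)} trajectory rows for {cities.shape[0]} cities x 5 scenarios")
    print(f"pointwise dominance who5<=who10<=who15<=policy<=baseline: {'OK' if ok else 'VIOLATED'}")
    mean_2030 = wide.reset_index().query("year == 2030")[order].mean()
    print("mean 2030 concentration (ug/m3):")
    for name, value in mean_2030.items():
        print(f"  {name:>9s}: {value:.2f}")


if __name__ == "__main__":
    main()
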