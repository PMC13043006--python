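import numpy as np
import pandas as pd
import pytest

from pm25hia import demography
from pm25hia.exposure_response import CRFRegistry
from pm25hia.scenario_engine import build_trajectories, default_scenarios
from pm25hia.synthetic_data import SyntheticConfig, generate_city_panel


@pytest.fixture(scope="session")
def registry() -> CRFRegistry:
    return CRFRegistry.default()


@pytest.fixture(scope="session")
def panel():
    """Default synthetic panel (337 cities, seed 0)."""
    return generate_city_panel(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_panel():
    """A 20-city panel for fast pipeline-level tests."""
    return generate_city_panel(SyntheticConfig(n_cities=20, seed=11))


@pytest.fixture(scope="session")
def small_inputs(small_panel):
    """Projected inputs (trajectories, rates, costs, SSP2 population)
    for the 20-city panel."""
    traj = build_trajectories(small_panel["cities"], default_scenarios())
    rates = demography.project_baseline_rate(small_panel["rate_history"])
    costs = demography.project_unit_costs(small_panel["cost_history"])
    pop = demography.project_population(
        small_panel["population"], small_panel["ssp_multipliers"], ssps=["SSP2"]
    )
    return {"trajectories": traj, "rates": rates, "costs": costs, "population": pop}


def toy_inputs(n_cities=2, pm=(40.0, 30.0), rate=0.01, pop=1_000_000.0):
    """Minimal hand-checkable panel: flat trajectories at the base value,
    flat rates, flat population, one region."""
    cities = pd.DataFrame(
        {
            "city_id": [f"t{i}" for i in range(n_cities)],
            "province": "P1",
            "region": "eastern",
            "key_region": "none",
            "pm25_2020": list(pm)[:n_cities],
        }
    )
    years = list(range(2020, 2031))
    traj = pd.DataFrame(
        [
            (c, "baseline", y, p)
            for c, p in zip(cities["city_id"], cities["pm25_2020"])
            for y in years
        ],
        columns=["city_id", "scenario", "year", "pm25"],
    )
    rates = pd.DataFrame(
        [("eastern", "NCD+LRI", "all-25plus", y, rate) for y in years],
        columns=["region", "cause", "age_group", "year", "rate"],
    )
    population = pd.DataFrame(
        [(c, "SSP2", y, "all-25plus", pop) for c in cities["city_id"] for y in years],
        columns=["city_id", "ssp", "year", "age_group", "persons"],
    )
    return cities, traj, rates, population
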