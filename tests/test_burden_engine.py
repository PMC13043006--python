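"""Health impact function, Monte Carlo aggregation, and averted-burden
bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import toy_inputs
from pm25hia.burden_engine import (
    UncertaintyConfig,
    attributable_events,
    averted_events,
    run_burden,
)
from pm25hia.errors import ConfigurationError, InputError
from pm25hia.exposure_response import CRFRegistry, GEMMParams, RelativeRisk
from pm25hia.scenario_engine import YEARS

TOY_GEMM = GEMMParams(theta=0.143, theta_se=0.018, alpha=1.6, mu=15.5, nu=36.8, cause="NCD+LRI")


def toy_registry(theta_se=0.018):
    reg = CRFRegistry()
    reg.gemm.append(
        GEMMParams(theta=0.143, theta_se=theta_se, alpha=1.6, mu=15.5, nu=36.8, cause="NCD+LRI")
    )
    return reg


class TestAttributableEvents:
    def test_forced_arithmetic(self):
        # AF = 0.25 corresponds to RR = 4/3
        rr = RelativeRisk(value=4.0 / 3.0, cause="NCD+LRI", concentration=30.0)
        assert attributable_events(0.008, rr, 100_000) == pytest.approx(200.0, rel=1e-12)

    def test_null_exposure(self):
        rr = RelativeRisk(value=1.0, cause="NCD+LRI", concentration=2.4)
        assert attributable_events(0.5, rr, 1e9) == 0.0

    def test_derived_example(self):
        rr = RelativeRisk(value=1.127376, cause="NCD+LRI", concentration=12.4)
        assert attributable_events(0.01, rr, 1_000_000) == pytest.approx(1129.85, abs=0.01)

    def test_negative_inputs_rejected(self):
        rr = RelativeRisk(value=1.2, cause="NCD+LRI", concentration=20.0)
        with pytest.raises(InputError):
            attributable_events(-0.01, rr, 1000)
        with pytest.raises(InputError):
            attributable_events(0.01, rr, -1000)


class TestRunBurdenOracle:
    def test_two_city_toy_matches_brute_force(self):
        """Full engine on a 2-city flat panel equals a spreadsheet-style
        recomputation with scalar math to 1e-9."""
        cities, traj, rates, pop = toy_inputs(pm=(40.0, 30.0), rate=0.01, pop=1_000_000.0)
        run = run_burden(
            cities, traj, pop, rates, toy_registry(),
            config=UncertaintyConfig(n_draws=10, seed=1),
        )
        result = run.aggregate(level="national", period=(2021, 2022))
        point = result["point"].iloc[0]

        expected = 0.0
        for conc in (40.0, 30.0):
            z = conc - 2.4
            w = 1.0 / (1.0 + math.exp(-(z - 15.5) / 36.8))
            rr = math.exp(0.143 * math.log(1 + z / 1.6) * w)
            expected += 2 * 0.01 * (rr - 1) / rr * 1_000_000  # 2 years
        assert point == pytest.approx(expected, rel=1e-9)

    def test_per_draw_aggregation_matches_brute_force(self):
        """Interval construction sums per-draw totals over cities; verify
        against direct recomputation from the sampled parameters on a
        3-city toy."""
        cities, traj, rates, pop = toy_inputs(n_cities=3, pm=(40.0, 30.0, 20.0))
        cfg = UncertaintyConfig(n_draws=50, seed=9)
        run = run_burden(cities, traj, pop, rates, toy_registry(), config=cfg)
        result = run.aggregate(level="national", period=(2021, 2030))

        draws = run.entries[0].draws
        totals = np.zeros(cfg.n_draws)
        for conc in (40.0, 30.0, 20.0):
            z = conc - 2.4
            w = 1.0 / (1.0 + math.exp(-(z - 15.5) / 36.8))
            h = math.log(1 + z / 1.6) * w
            totals += 10 * 0.01 * (1 - np.exp(-draws * h)) * 1_000_000
        assert result["lower"].iloc[0] == pytest.approx(np.percentile(totals, 2.5), rel=1e-9)
        assert result["upper"].iloc[0] == pytest.approx(np.percentile(totals, 97.5), rel=1e-9)

    def test_identical_cities_double_the_total(self):
        cities, traj, rates, pop = toy_inputs(pm=(35.0, 35.0))
        run2 = run_burden(cities, traj, pop, rates, toy_registry(),
                          config=UncertaintyConfig(n_draws=5, seed=3))
        both = run2.aggregate(level="national")["point"].iloc[0]
        single = run2.aggregate(level="city")["point"].iloc[0]
        assert both == pytest.approx(2 * single, rel=1e-12)

    def test_degenerate_uncertainty_collapses_interval(self):
        cities, traj, rates, pop = toy_inputs()
        run = run_burden(cities, traj, pop, rates, toy_registry(theta_se=0.0),
                         config=UncertaintyConfig(n_draws=1, seed=0))
        res = run.aggregate(level="national")
        assert res["lower"].iloc[0] == pytest.approx(res["point"].iloc[0], rel=1e-12)
        assert res["upper"].iloc[0] == pytest.approx(res["point"].iloc[0], rel=1e-12)

    def test_af_bound_events_below_rate_times_pop(self, small_panel, small_inputs, registry):
        run = run_burden(
            small_panel["cities"], small_inputs["trajectories"], small_inputs["population"],
            small_inputs["rates"], registry, config=UncertaintyConfig(n_draws=2, seed=0),
        )
        cells = run.cells()
        # rate x pop upper bound per cell, reconstructed from stored matrices
        for k, ent in enumerate(run.entries):
            rp = run._rp[("SSP2", k)]
            for sc in run.scenarios:
                sub = cells[(cells["cause"] == ent.cause) & (cells["scenario"] == sc)]
                events = sub["attributable_events"].to_numpy().reshape(rp.shape)
                assert np.all(events <= rp + 1e-9)

    def test_point_inside_interval_everywhere(self, small_panel, small_inputs, registry):
        run = run_burden(
            small_panel["cities"], small_inputs["trajectories"], small_inputs["population"],
            small_inputs["rates"], registry, config=UncertaintyConfig(n_draws=400, seed=2),
        )
        res = run.aggregate(level="national", include_years=True)
        assert (res["lower"] <= res["point"] + 1e-9).all()
        assert (res["point"] <= res["upper"] + 1e-9).all()

    def test_interval_width_shrinks_with_theta_se(self):
        cities, traj, rates, pop = toy_inputs()
        widths = []
        for se in (0.02, 0.002):
            run = run_burden(cities, traj, pop, rates, toy_registry(theta_se=se),
                             config=UncertaintyConfig(n_draws=500, seed=4))
            res = run.aggregate(level="national")
            widths.append(res["upper"].iloc[0] - res["lower"].iloc[0])
        assert widths[1] < widths[0] / 5

    def test_deterministic_given_seed(self):
        cities, traj, rates, pop = toy_inputs()
        cfg = UncertaintyConfig(n_draws=100, seed=123)
        r1 = run_burden(cities, traj, pop, rates, toy_registry(), config=cfg).aggregate()
        r2 = run_burden(cities, traj, pop, rates, toy_registry(), config=cfg).aggregate()
        pd.testing.assert_frame_equal(r1, r2)
        assert (r1["lower"] == r2["lower"]).all() and (r1["upper"] == r2["upper"]).all()

    def test_missing_rates_for_cause_rejected(self):
        cities, traj, rates, pop = toy_inputs()
        reg = toy_registry()
        reg.gemm.append(
            GEMMParams(theta=0.29, theta_se=0.01, alpha=1.9, mu=12.0, nu=40.2, cause="IHD")
        )
        with pytest.raises(ConfigurationError, match="IHD"):
            run_burden(cities, traj, pop, rates, reg,
                       config=UncertaintyConfig(n_draws=2, seed=0))


@pytest.fixture(scope="module")
def small_run(small_panel, small_inputs, registry):
    return run_burden(
        small_panel["cities"], small_inputs["trajectories"], small_inputs["population"],
        small_inputs["rates"], registry, config=UncertaintyConfig(n_draws=50, seed=6),
    )


class TestAvertedEvents:

    def test_self_difference_is_zero(self, small_run):
        agg = small_run.aggregate(level="national")
        base = agg[agg["scenario"] == "baseline"]
        av = averted_events(base, base)
        assert np.allclose(av["averted"], 0.0)

    def test_period_total_and_annual_average(self):
        cities, traj, rates, pop = toy_inputs()
        frame = pd.DataFrame(
            {
                "scenario": ["baseline"], "ssp": ["SSP2"], "level": ["national"],
                "geography": ["national"], "family": ["gemm"], "cause": ["NCD+LRI"],
                "year": ["2021-2030"], "point": [100.0], "lower": [90.0], "upper": [110.0],
            }
        )
        scen = frame.assign(scenario="policy", point=70.0)
        av = averted_events(frame, scen)
        assert av["averted"].iloc[0] == pytest.approx(30.0)
        assert av["annual_average"].iloc[0] == pytest.approx(3.0)

    def test_key_mismatch_rejected(self, small_run):
        agg = small_run.aggregate(level="national")
        base = agg[agg["scenario"] == "baseline"]
        scen = agg[agg["scenario"] == "policy"].iloc[1:]
        with pytest.raises(InputError):
            averted_events(base, scen)

    def test_dominated_scenarios_avert_nonnegative_everywhere(self, small_run):
        agg = pd.concat(
            [small_run.aggregate(level="city", include_years=True)], ignore_index=True
        )
        base = agg[agg["scenario"] == "baseline"]
        for sc in ("policy", "who15", "who10", "who5"):
            av = averted_events(base, agg[agg["scenario"] == sc])
            assert (av["averted"] >= -1e-9).all()

    def test_conservation_baseline_equals_scenario_plus_averted(self, small_run):
        agg = small_run.aggregate(level="national", include_years=True)
        base = agg[agg["scenario"] == "baseline"]
        for sc in ("policy", "who5"):
            scen = agg[agg["scenario"] == sc]
            av = averted_events(base, scen)
            lhs = base.sort_values(["cause", "year"])["point"].to_numpy()
            rhs = (
                av.sort_values(["cause", "year"])[["point", "averted"]].sum(axis=1).to_numpy()
            )
            assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-9)


class TestScenarioMonotonicity:
    def test_cumulative_deaths_ordering(self, small_panel, small_inputs, registry):
        run = run_burden(
            small_panel["cities"], small_inputs["trajectories"], small_inputs["population"],
            small_inputs["rates"], registry, config=UncertaintyConfig(n_draws=2, seed=0),
        )
        res = run.aggregate(level="national")
        tot = res[res["cause"] == "NCD+LRI"].set_index("scenario")["point"]
        assert tot["who5"] <= tot["who10"] <= tot["who15"] <= tot["policy"] <= tot["baseline"]


class TestUncertaintyConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ConfigurationError):
            UncertaintyConfig(n_draws=0)
        with pytest.raises(ConfigurationError):
            UncertaintyConfig(interval=1.0)
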