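"""Attributable-burden computation: the health impact function applied
per city x year x cause x scenario, with Monte Carlo uncertainty.

The impact function is

    dy = x0 * (RR - 1)/RR * Pop

with baseline rate x0, relative risk RR from the concentration-response
registry, and population at risk Pop. Writing AF = 1 - exp(-p * h) with
hazard shape h (GEMM: log(1+z/alpha)*w(z); log-linear: z - z0) and slope
parameter p (theta or beta), point estimates use the central parameter
and intervals come from seeded normal parameter draws (theta truncated
at zero; beta's SE derived from its 95% CI). Only CRF parameter
uncertainty is propagated; rates and populations are treated as fixed.

Intervals for aggregates are formed by summing per-draw totals over the
aggregation group before taking percentiles — never by summing interval
bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .exposure_response import (
    DEFAULT_COUNTERFACTUAL,
    CRFRegistry,
    GEMMParams,
    LogLinearParams,
    RelativeRisk,
    attributable_fraction,
    counterfactual_transform,
    gemm_log_hazard,
)
from .scenario_engine import YEARS

ALL_AGES = "all-25plus"
PERIOD_DEFAULT = (2021, 2030)

LEVELS = ("city", "province", "region", "key_region", "national")


@dataclass(frozen=True)
class UncertaintyConfig:
    """Monte Carlo settings: number of parameter draws, seed, and the
    two-sided coverage of the reported interval."""

    n_draws: int = 1000
    seed: int = 0
    interval: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ConfigurationError(f"n_draws must be >= 1, got {self.n_draws}")
        if not (0 < self.interval < 1):
            raise ConfigurationError(f"interval must be in (0, 1), got {self.interval}")


def attributable_events(rate: float, rr: Union[RelativeRisk, float], pop: float) -> float:
    """dy = x0 * (RR-1)/RR * Pop for one cell."""
    if rate < 0 or pop < 0:
        raise InputError("rate and population must be nonnegative")
    return rate * attributable_fraction(rr) * pop


@dataclass
class _Entry:
    """One registry row prepared for vectorized evaluation."""

    family: str  # "gemm" | "loglinear"
    cause: str
    age_group: str
    point_param: float
    draws: np.ndarray  # (n_draws,) sampled slope parameters
    params: object


class BurdenRun:
    """Result container keeping enough structure for exact per-draw
    aggregation at any geographic level.

    Stores, per scenario and registry entry, the hazard-shape matrix
    h (city x year), and per SSP and entry the rate x population matrix
    RP (city x year); attributable events are RP * (1 - exp(-p h)).
    """

    def __init__(
        self,
        cities: pd.DataFrame,
        scenarios: Sequence[str],
        ssps: Sequence[str],
        entries: list[_Entry],
        hazards: dict,
        ratepops: dict,
        config: UncertaintyConfig,
    ) -> None:
        self.cities = cities.reset_index(drop=True)
        self.scenarios = list(scenarios)
        self.ssps = list(ssps)
        self.entries = entries
        self._h = hazards  # (scenario, entry_idx) -> (n_city, n_year)
        self._rp = ratepops  # (ssp, entry_idx) -> (n_city, n_year)
        self.config = config
        self.years = np.asarray(YEARS)

    # -- point estimates ----------------------------------------------------

    def cells(self, family: Optional[str] = None) -> pd.DataFrame:
        """Tidy point-estimate table: one row per scenario x ssp x city x
        year x cause x age_group, with attributable events and the RR used."""
        rows = []
        for sc in self.scenarios:
            for ssp in self.ssps:
                for k, ent in enumerate(self.entries):
                    if family and ent.family != family:
                        continue
                    h = self._h[(sc, k)]
                    rp = self._rp[(ssp, k)]
                    af = 1.0 - np.exp(-ent.point_param * h)
                    events = rp * af
                    rr = np.exp(ent.point_param * h)
                    frame = pd.DataFrame(
                        {
                            "city_id": np.repeat(self.cities["city_id"].to_numpy(), len(YEARS)),
                            "year": np.tile(self.years, len(self.cities)),
                            "attributable_events": events.ravel(),
                            "rr_used": rr.ravel(),
                        }
                    )
                    frame.insert(0, "scenario", sc)
                    frame.insert(1, "ssp", ssp)
                    frame.insert(2, "cause", ent.cause)
                    frame.insert(3, "age_group", ent.age_group)
                    rows.append(frame)
        return pd.concat(rows, ignore_index=True)

    # -- aggregation with per-draw intervals --------------------------------

    def _group_indices(self, level: str) -> list[tuple[str, np.ndarray]]:
        if level == "national":
            return [("national", np.arange(len(self.cities)))]
        if level == "city":
            col = "city_id"
        elif level in ("province", "region", "key_region"):
            col = level
        else:
            raise ConfigurationError(f"unknown aggregation level {level!r}; use one of {LEVELS}")
        if col not in self.cities.columns:
            raise InputError(f"city table lacks a {col!r} column for aggregation")
        groups = []
        for name, idx in self.cities.groupby(col, sort=True).indices.items():
            groups.append((str(name), np.asarray(idx)))
        return groups

    def aggregate(
        self,
        level: str = "national",
        period: tuple[int, int] = PERIOD_DEFAULT,
        include_years: bool = False,
        families: Iterable[str] = ("gemm", "loglinear"),
    ) -> pd.DataFrame:
        """Sum events over cities of each geography and over the period.

        Returns tidy rows (scenario, ssp, level, geography, cause, year,
        point, lower, upper); ``year`` is the calendar year for per-year
        rows and "Y0-Y1" for the period total. Intervals are percentiles
        of per-draw aggregated totals.
        """
        lo_q = 100 * (1 - self.config.interval) / 2
        hi_q = 100 - lo_q
        ymask = (self.years >= period[0]) & (self.years <= period[1])
        yrs = self.years[ymask]
        period_label = f"{period[0]}-{period[1]}"
        families = set(families)

        by_cause: dict[tuple[str, str], list[int]] = {}
        for k, ent in enumerate(self.entries):
            if ent.family in families:
                by_cause.setdefault((ent.family, ent.cause), []).append(k)

        groups = self._group_indices(level)
        records = []
        for sc in self.scenarios:
            for ssp in self.ssps:
                for (family, cause), ks in by_cause.items():
                    for geo, idx in groups:
                        n_draws = self.config.n_draws
                        point_y = np.zeros(len(yrs))
                        draws_y = np.zeros((n_draws, len(yrs)))
                        for k in ks:
                            h = self._h[(sc, k)][idx][:, ymask]
                            rp = self._rp[(ssp, k)][idx][:, ymask]
                            ent = self.entries[k]
                            point_y += np.sum(rp * (1.0 - np.exp(-ent.point_param * h)), axis=0)
                            # (d, g, y): AF per draw, summed over cities
                            af_d = 1.0 - np.exp(
                                -ent.draws[:, None, None] * h[None, :, :]
                            )
                            draws_y += np.einsum("dgy,gy->dy", af_d, rp)
                        if include_years:
                            lo = np.percentile(draws_y, lo_q, axis=0)
                            hi = np.percentile(draws_y, hi_q, axis=0)
                            for j, year in enumerate(yrs):
                                records.append(
                                    (sc, ssp, level, geo, family, cause, str(year),
                                     point_y[j], lo[j], hi[j])
                                )
                        tot_d = draws_y.sum(axis=1)
                        records.append(
                            (sc, ssp, level, geo, family, cause, period_label,
                             float(point_y.sum()),
                             float(np.percentile(tot_d, lo_q)),
                             float(np.percentile(tot_d, hi_q)))
                        )
        return pd.DataFrame(
            records,
            columns=["scenario", "ssp", "level", "geography", "family", "cause",
                     "year", "point", "lower", "upper"],
        )


_RESULT_KEYS = ["ssp", "level", "geography", "family", "cause", "year"]


def averted_events(baseline: pd.DataFrame, scenario: pd.DataFrame) -> pd.DataFrame:
    """Averted burden: baseline point minus scenario point, per cell.

    Both inputs are aggregate tables from :meth:`BurdenRun.aggregate`
    restricted to a single scenario each; grouping keys must match
    exactly. Period rows additionally carry an ``annual_average`` column
    (period total divided by the number of years).
    """
    b = baseline.set_index(_RESULT_KEYS).sort_index()
    s = scenario.set_index(_RESULT_KEYS).sort_index()
    if not b.index.equals(s.index):
        raise InputError("baseline and scenario results have mismatched grouping keys")
    out = s.reset_index()[_RESULT_KEYS].copy()
    out.insert(0, "scenario", scenario["scenario"].iloc[0] if len(scenario) else "")
    out["point"] = s["point"].to_numpy()
    out["lower"] = s["lower"].to_numpy()
    out["upper"] = s["upper"].to_numpy()
    out["averted"] = b["point"].to_numpy() - s["point"].to_numpy()
    n_years = out["year"].map(_period_years)
    out["annual_average"] = out["averted"] / n_years
    return out


def _period_years(label: str) -> int:
    if "-" in str(label):
        y0, y1 = str(label).split("-")
        return int(y1) - int(y0) + 1
    return 1


def _sample_draws(entry_params, index: int, config: UncertaintyConfig) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))
    if isinstance(entry_params, GEMMParams):
        draws = rng.normal(entry_params.theta, entry_params.theta_se, size=config.n_draws)
        return np.maximum(draws, 0.0)  # theta truncated at zero
    draws = rng.normal(entry_params.beta, entry_params.beta_se, size=config.n_draws)
    return draws


def _rate_matrix(
    rates: pd.DataFrame, cause: str, band: str, cities: pd.DataFrame
) -> np.ndarray:
    """(n_city, n_year) baseline rates, looked up by each city's region."""
    sub = rates[(rates["cause"] == cause) & (rates["age_group"] == band)]
    if sub.empty:
        raise ConfigurationError(f"no baseline rates for cause {cause!r}, age group {band!r}")
    pivot = sub.pivot_table(index="region", columns="year", values="rate")
    missing_years = [y for y in YEARS if y not in pivot.columns]
    if missing_years:
        raise InputError(f"baseline rates for {cause!r} missing years {missing_years}")
    missing_regions = set(cities["region"]) - set(pivot.index)
    if missing_regions:
        raise InputError(f"baseline rates for {cause!r} missing regions {sorted(missing_regions)}")
    return pivot.loc[cities["region"], list(YEARS)].to_numpy()


def run_burden(
    cities: pd.DataFrame,
    trajectories: pd.DataFrame,
    population: pd.DataFrame,
    rates: pd.DataFrame,
    registry: CRFRegistry,
    config: Optional[UncertaintyConfig] = None,
    scenarios: Optional[Sequence[str]] = None,
    ssps: Optional[Sequence[str]] = None,
    counterfactual: float = DEFAULT_COUNTERFACTUAL,
) -> BurdenRun:
    """Evaluate the impact function over the whole panel.

    ``cities``: (city_id, region, ...); ``trajectories``: long format
    (city_id, scenario, year, pm25); ``population``: (city_id, ssp, year,
    age_group, persons); ``rates``: (region, cause, age_group, year,
    rate) covering 2020-2030 for every registry cause and endpoint.

    Parameter draws are generated once per registry entry from the
    configured seed and shared across scenarios and SSPs, so scenario
    contrasts are evaluated on paired draws and the whole run is
    deterministic given the seed.
    """
    config = config or UncertaintyConfig()
    cities = cities.reset_index(drop=True)
    scenarios = list(scenarios) if scenarios is not None else sorted(
        trajectories["scenario"].unique()
    )
    ssps = list(ssps) if ssps is not None else sorted(population["ssp"].unique())

    registry.require(
        [p.cause for p in registry.gemm], [p.endpoint for p in registry.loglinear]
    )
    entries: list[_Entry] = []
    for p in registry.gemm:
        entries.append(_Entry("gemm", p.cause, p.age_group, p.theta, None, p))
    for p in registry.loglinear:
        entries.append(_Entry("loglinear", p.endpoint, ALL_AGES, p.beta, None, p))
    for k, ent in enumerate(entries):
        ent.draws = _sample_draws(ent.params, k, config)

    # concentration matrices per scenario
    conc = {}
    for sc in scenarios:
        sub = trajectories[trajectories["scenario"] == sc]
        if sub.empty:
            raise ConfigurationError(f"no trajectories for scenario {sc!r}")
        pivot = sub.pivot_table(index="city_id", columns="year", values="pm25")
        missing = set(cities["city_id"]) - set(pivot.index)
        if missing:
            raise InputError(f"trajectories for scenario {sc!r} missing cities {sorted(missing)[:5]}")
        conc[sc] = pivot.loc[cities["city_id"], list(YEARS)].to_numpy()

    # population matrices per (ssp, band) and totals
    bands = sorted(population["age_group"].unique())
    pop_mat: dict[tuple[str, str], np.ndarray] = {}
    pop_total: dict[str, np.ndarray] = {}
    for ssp in ssps:
        sub = population[population["ssp"] == ssp]
        if sub.empty:
            raise ConfigurationError(f"no population projection for SSP {ssp!r}")
        total = np.zeros((len(cities), len(YEARS)))
        for band in bands:
            piv = sub[sub["age_group"] == band].pivot_table(
                index="city_id", columns="year", values="persons"
            )
            mat = piv.reindex(index=cities["city_id"], columns=list(YEARS)).to_numpy()
            if np.isnan(mat).any():
                raise InputError(f"population for SSP {ssp!r}, band {band!r} has gaps")
            pop_mat[(ssp, band)] = mat
            total += mat
        pop_total[ssp] = total

    # hazard-shape matrices per (scenario, entry)
    hazards = {}
    for sc in scenarios:
        c = conc[sc]
        for k, ent in enumerate(entries):
            if ent.family == "gemm":
                z = counterfactual_transform(c, counterfactual)
                hazards[(sc, k)] = gemm_log_hazard(z, ent.params)
            else:
                hazards[(sc, k)] = np.maximum(0.0, c - ent.params.z0)

    # rate x population matrices per (ssp, entry)
    ratepops = {}
    for ssp in ssps:
        for k, ent in enumerate(entries):
            if ent.age_group == ALL_AGES:
                applicable = sorted(
                    rates.loc[rates["cause"] == ent.cause, "age_group"].unique()
                )
                if not applicable:
                    raise ConfigurationError(
                        f"no baseline rates for cause {ent.cause!r} in the rate table"
                    )
            else:
                applicable = [ent.age_group]
            rp = np.zeros((len(cities), len(YEARS)))
            for band in applicable:
                rmat = _rate_matrix(rates, ent.cause, band, cities)
                pmat = pop_total[ssp] if band == ALL_AGES else pop_mat.get((ssp, band))
                if pmat is None:
                    raise InputError(
                        f"population table lacks age group {band!r} needed by "
                        f"cause {ent.cause!r}"
                    )
                rp += rmat * pmat
            ratepops[(ssp, k)] = rp

    return BurdenRun(cities, scenarios, ssps, entries, hazards, ratepops, config)
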