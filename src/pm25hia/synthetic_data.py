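"""Synthetic China-like city panel generator.

Every downstream stage is exercised on generated data with the
statistical structure the analysis assumes: 337 prefecture-level cities
whose 2020 annual-mean PM2.5 lies in [7, 63] ug/m3 with a national mean
of 32.6 ug/m3 and an east-skewed distribution; heavy-tailed (lognormal)
adult populations with a fixed 5-year age structure from 25-29 to 80+;
region-specific (western/central/eastern) cause- and age-specific
baseline mortality rates with log-linear historical trends; admission
incidence and unit-cost histories for trend projection; and national
SSP population multipliers bracketing SSP2 as flat.

Magnitudes are chosen to be demographically realistic for a panel
covering roughly 70% of China's population (about 0.6 billion adults
25+, cause rates at national burden-of-disease magnitudes); they do not
reproduce the true 2020 exposure map. Everything is deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

AGE_BANDS = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: Fixed adult age shares (sum to 1), a middle-aged-heavy structure.
AGE_SHARES = np.array(
    [0.105, 0.110, 0.115, 0.120, 0.105, 0.100, 0.095, 0.080, 0.065, 0.050, 0.033, 0.022]
)

REGIONS = ("western", "central", "eastern")

#: Mortality higher in the west, admissions likewise; multiplicative.
REGION_RATE_FACTOR = {"western": 1.10, "central": 1.05, "eastern": 0.95}
REGION_POP_FACTOR = {"western": 0.70, "central": 1.00, "eastern": 1.40}

#: 2020 mean event rate per 25+ person-year, annual log trend, and
#: per-5-year-band age gradient for each mortality cause.
DEFAULT_RATE_PARAMS = {
    "NCD+LRI": {"mean": 0.0105, "trend": -0.005, "age_gradient": 1.55},
    "stroke": {"mean": 0.0022, "trend": -0.010, "age_gradient": 1.60},
    "IHD": {"mean": 0.0019, "trend": 0.010, "age_gradient": 1.60},
    "COPD": {"mean": 0.0010, "trend": -0.030, "age_gradient": 1.70},
    "LC": {"mean": 0.00065, "trend": 0.010, "age_gradient": 1.45},
    "LRI": {"mean": 0.00025, "trend": -0.030, "age_gradient": 1.50},
}

#: Hospital-admission incidence per 25+ person-year (no age gradient).
DEFAULT_ADMISSION_PARAMS = {
    "cardiovascular": {"mean": 0.015, "trend": 0.020},
    "respiratory": {"mean": 0.012, "trend": 0.020},
}

#: Per-admission direct cost in 2020 USD and its annual log trend.
DEFAULT_COST_PARAMS = {
    "cardiovascular": {"cost_2020": 1800.0, "trend": 0.030},
    "respiratory": {"cost_2020": 1150.0, "trend": 0.030},
}

#: Constant year-over-year national population multipliers per SSP;
#: SSP2 ("middle of the road") is flat, SSP3 grows, SSP5 shrinks most.
DEFAULT_SSP_MULTIPLIERS = {
    "SSP1": 0.9990,
    "SSP2": 1.0000,
    "SSP3": 1.0015,
    "SSP4": 0.9985,
    "SSP5": 0.9980,
}

HISTORY_YEARS = tuple(range(2015, 2021))


@dataclass(frozen=True)
class SyntheticConfig:
    """Calibration constants for the generated panel."""

    n_cities: int = 337
    pm_min: float = 7.0
    pm_max: float = 63.0
    pm_mean_target: float = 32.6
    #: additive east-west spread as a fraction of the mean target:
    #: eastern cities shifted up by gradient*mean/2, western down.
    east_gradient: float = 0.5
    #: lognormal (median, sigma) of 25+ city population.
    pop_median: float = 1.1e6
    pop_sigma: float = 0.85
    region_shares: tuple[float, float, float] = (0.30, 0.30, 0.40)
    rate_noise_sd: float = 0.01
    rate_params: dict = field(default_factory=lambda: dict(DEFAULT_RATE_PARAMS))
    admission_params: dict = field(default_factory=lambda: dict(DEFAULT_ADMISSION_PARAMS))
    cost_params: dict = field(default_factory=lambda: dict(DEFAULT_COST_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pm_min < self.pm_mean_target < self.pm_max):
            raise ConfigurationError(
                "infeasible calibration: pm_mean_target must lie strictly "
                f"inside [{self.pm_min}, {self.pm_max}]"
            )
        if abs(sum(self.region_shares) - 1.0) > 1e-9:
            raise ConfigurationError("region shares must sum to 1")
        if self.n_cities < 1:
            raise ConfigurationError("n_cities must be >= 1")


def _provinces_for(region: str) -> list[str]:
    counts = {"western": 10, "central": 9, "eastern": 12}
    prefix = region[0].upper()
    return [f"{prefix}{i:02d}" for i in range(1, counts[region] + 1)]


_KEY_REGION = {"E01": "BTH", "E02": "BTH", "E03": "YDR", "E04": "YDR", "C01": "FP", "C02": "FP"}


def _draw_pm25(rng: np.random.Generator, cfg: SyntheticConfig, regions: np.ndarray) -> np.ndarray:
    """Truncated-lognormal draw with an eastern mean shift, calibrated so
    the panel mean hits the target while staying inside [pm_min, pm_max]."""
    n = len(regions)
    mu = np.log(cfg.pm_mean_target) - 0.08  # median a touch below the mean
    x = rng.lognormal(mean=mu, sigma=0.35, size=n)
    for _ in range(100):  # rejection-truncate into the admissible range
        out = (x < cfg.pm_min) | (x > cfg.pm_max)
        if not out.any():
            break
        x[out] = rng.lognormal(mean=mu, sigma=0.35, size=int(out.sum()))
    x = np.clip(x, cfg.pm_min, cfg.pm_max)

    shift = cfg.east_gradient * cfg.pm_mean_target / 2.0
    x = x + np.where(regions == "eastern", shift, np.where(regions == "western", -shift, 0.0))
    x = np.clip(x, cfg.pm_min, cfg.pm_max)
    for _ in range(200):  # re-center the panel mean onto the target
        delta = cfg.pm_mean_target - x.mean()
        if abs(delta) < 1e-10:
            break
        x = np.clip(x + delta, cfg.pm_min, cfg.pm_max)
    return x


def _banded_rates(mean_rate: float, gradient: float) -> np.ndarray:
    """Age-band rates r_b = r0 * g^b whose share-weighted mean equals
    the configured all-adult mean rate."""
    ladder = gradient ** np.arange(len(AGE_BANDS))
    r0 = mean_rate / float(AGE_SHARES @ ladder)
    return r0 * ladder


def generate_city_panel(config: Optional[SyntheticConfig] = None) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic input bundle.

    Returns a dict of DataFrames with the same schemas the real-data
    readers consume: ``cities`` (city_id, province, region, key_region,
    pm25_2020), ``population`` (city_id, age_group, persons_2020),
    ``rate_history`` (region, cause, age_group, year, rate) covering
    mortality causes and admission endpoints, ``cost_history``
    (endpoint, year, cost_usd), and ``ssp_multipliers`` (ssp, year,
    multiplier).
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # -- cities -------------------------------------------------------------
    n = cfg.n_cities
    counts = np.floor(np.asarray(cfg.region_shares) * n).astype(int)
    counts[-1] = n - counts[:-1].sum()
    regions = np.repeat(REGIONS, counts)
    provinces = np.array(
        [rng.choice(_provinces_for(r)) for r in regions]
    )
    pm25 = _draw_pm25(rng, cfg, regions)
    cities = pd.DataFrame(
        {
            "city_id": [f"city{i:03d}" for i in range(1, n + 1)],
            "province": provinces,
            "region": regions,
            "key_region": [_KEY_REGION.get(p, "none") for p in provinces],
            "pm25_2020": pm25,
        }
    )

    # -- population ---------------------------------------------------------
    factor = np.array([REGION_POP_FACTOR[r] for r in regions])
    adults = rng.lognormal(mean=np.log(cfg.pop_median), sigma=cfg.pop_sigma, size=n) * factor
    population = pd.DataFrame(
        {
            "city_id": np.repeat(cities["city_id"].to_numpy(), len(AGE_BANDS)),
            "age_group": np.tile(AGE_BANDS, n),
            "persons_2020": np.repeat(adults, len(AGE_BANDS)) * np.tile(AGE_SHARES, n),
        }
    )

    # -- baseline rate histories (mortality causes, per age band) -----------
    records = []
    for cause, p in cfg.rate_params.items():
        banded = _banded_rates(p["mean"], p["age_gradient"])
        for region in REGIONS:
            rf = REGION_RATE_FACTOR[region]
            for band, r2020 in zip(AGE_BANDS, banded):
                noise = rng.normal(0.0, cfg.rate_noise_sd, size=len(HISTORY_YEARS))
                for year, eps in zip(HISTORY_YEARS, noise):
                    records.append(
                        (region, cause, band, year,
                         r2020 * rf * np.exp(p["trend"] * (year - 2020) + eps))
                    )
    # admission endpoints: one all-adult band per region
    for endpoint, p in cfg.admission_params.items():
        for region in REGIONS:
            rf = REGION_RATE_FACTOR[region]
            noise = rng.normal(0.0, cfg.rate_noise_sd, size=len(HISTORY_YEARS))
            for year, eps in zip(HISTORY_YEARS, noise):
                records.append(
                    (region, endpoint, "all-25plus", year,
                     p["mean"] * rf * np.exp(p["trend"] * (year - 2020) + eps))
                )
    rate_history = pd.DataFrame(records, columns=["region", "cause", "age_group", "year", "rate"])

    # -- unit cost histories ------------------------------------------------
    cost_records = []
    for endpoint, p in cfg.cost_params.items():
        noise = rng.normal(0.0, cfg.rate_noise_sd, size=len(HISTORY_YEARS))
        for year, eps in zip(HISTORY_YEARS, noise):
            cost_records.append(
                (endpoint, year, p["cost_2020"] * np.exp(p["trend"] * (year - 2020) + eps))
            )
    cost_history = pd.DataFrame(cost_records, columns=["endpoint", "year", "cost_usd"])

    # -- SSP multipliers ----------------------------------------------------
    ssp_rows = [
        (ssp, year, mult)
        for ssp, mult in DEFAULT_SSP_MULTIPLIERS.items()
        for year in range(2021, 2031)
    ]
    ssp_multipliers = pd.DataFrame(ssp_rows, columns=["ssp", "year", "multiplier"])

    return {
        "cities": cities,
        "population": population,
        "rate_history": rate_history,
        "cost_history": cost_history,
        "ssp_multipliers": ssp_multipliers,
    }


def generate_monitor_readings(
    cities: pd.DataFrame,
    stations_per_city: tuple[int, int] = (2, 5),
    seed: int = 0,
    freq: str = "D",
    noise_sd: float = 1.0,
    station_sd: float = 2.0,
) -> pd.DataFrame:
    """Synthetic station-level PM2.5 series for the 2020 base year.

    Each city gets a station count drawn uniformly from
    ``stations_per_city``; station-level offsets are mean-centered within
    the city so that two-stage aggregation (station annual means, then
    the unweighted across-station mean) recovers the city annual mean up
    to the sampling error of the observation noise. Daily resolution by
    default; pass ``freq="h"`` for hourly.
    """
    if cities.empty:
        raise InputError("city table is empty")
    rng = np.random.default_rng(seed)
    stamps = pd.date_range("2020-01-01", "2020-12-31 23:00", freq=freq)
    lo, hi = stations_per_city
    frames = []
    for city_id, mean in zip(cities["city_id"], cities["pm25_2020"]):
        n_stations = int(rng.integers(lo, hi + 1))
        offsets = rng.normal(0.0, station_sd, size=n_stations)
        offsets -= offsets.mean()  # offsets average out exactly within the city
        for j, off in enumerate(offsets):
            vals = mean + off + rng.normal(0.0, noise_sd, size=len(stamps))
            frames.append(
                pd.DataFrame(
                    {
                        "station_id": f"{city_id}-S{j + 1}",
                        "city_id": city_id,
                        "timestamp": stamps,
                        "pm25": vals,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
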