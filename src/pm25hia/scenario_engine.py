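"""Per-city annual PM2.5 trajectories, 2020-2030, under policy scenarios.

Five scenarios are modeled:

* ``baseline`` — concentrations held at 2020 levels through 2030;
* ``policy``   — the national clean-air plan: a 10% reduction by 2025,
  then decline toward a 25 ug/m3 ceiling by 2030;
* ``who15`` / ``who10`` / ``who5`` — WHO interim targets III and IV and
  the final air-quality guideline, each reached by 2030.

Paths between anchor years are linear (a steady decline). Targets act as
ceilings, never prescriptions: a city already below a target keeps its
current path rather than rising to meet it. The WHO trajectories are the
pointwise minimum of the enacted policy path and a straight glide from
the 2020 level to the target, which guarantees that tightening the
target never yields a higher concentration in any city-year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

BASE_YEAR = 2020
END_YEAR = 2030
YEARS: tuple[int, ...] = tuple(range(BASE_YEAR, END_YEAR + 1))

SSP_LABELS = ("SSP1", "SSP2", "SSP3", "SSP4", "SSP5")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named air-quality rule.

    ``terminal_target`` (ug/m3) is the 2030 ceiling; ``interim_reduction``
    is the fractional cut required by ``interim_year`` (policy scenario
    only). The baseline scenario has neither.
    """

    name: str
    terminal_target: Optional[float] = None
    terminal_year: int = END_YEAR
    interim_reduction: Optional[float] = None
    interim_year: int = 2025

    def __post_init__(self) -> None:
        if self.interim_reduction is not None and not (0 <= self.interim_reduction < 1):
            raise ConfigurationError(
                f"interim_reduction must be in [0, 1), got {self.interim_reduction}"
            )
        if self.terminal_target is not None and self.terminal_target <= 0:
            raise ConfigurationError(
                f"terminal_target must be > 0, got {self.terminal_target}"
            )
        if self.interim_year >= self.terminal_year:
            raise ConfigurationError("interim_year must precede terminal_year")


def default_scenarios() -> dict[str, ScenarioSpec]:
    """The five study scenarios with their published anchors."""
    return {
        "baseline": ScenarioSpec(name="baseline"),
        "policy": ScenarioSpec(name="policy", interim_reduction=0.10, terminal_target=25.0),
        "who15": ScenarioSpec(name="who15", terminal_target=15.0),
        "who10": ScenarioSpec(name="who10", terminal_target=10.0),
        "who5": ScenarioSpec(name="who5", terminal_target=5.0),
    }


@dataclass(frozen=True)
class ConcentrationTrajectory:
    """Annual mean PM2.5 for one city under one scenario, 2020-2030."""

    city_id: str
    scenario: str
    values: tuple[float, ...]
    years: tuple[int, ...] = YEARS

    def __post_init__(self) -> None:
        if len(self.values) != len(self.years):
            raise InputError(
                f"trajectory must cover {len(self.years)} years, got {len(self.values)}"
            )
        if any(v <= 0 for v in self.values):
            raise InputError("trajectory values must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def value_in(self, year: int) -> float:
        return self.values[self.years.index(year)]


def _segment(start_year: int, start: float, end_year: int, end: float) -> np.ndarray:
    """Linear interpolation inclusive of both endpoints."""
    n = end_year - start_year
    return start + (end - start) * np.arange(n + 1) / n


def _policy_path(base: float, spec: ScenarioSpec) -> np.ndarray:
    interim = base * (1.0 - (spec.interim_reduction or 0.0))
    terminal = min(spec.terminal_target, interim) if spec.terminal_target else interim
    first = _segment(BASE_YEAR, base, spec.interim_year, interim)
    second = _segment(spec.interim_year, interim, spec.terminal_year, terminal)
    return np.concatenate([first, second[1:]])


def build_trajectory(
    base_concentration: float,
    spec: ScenarioSpec,
    city_id: str = "",
    policy_spec: Optional[ScenarioSpec] = None,
) -> ConcentrationTrajectory:
    """Construct one city's 2020-2030 concentration path.

    WHO-target scenarios take the pointwise minimum of the enacted policy
    path (``policy_spec``, defaulting to the standard policy rule) and a
    linear glide from the base value to min(target, base) at 2030.
    """
    base = float(base_concentration)
    if base <= 0:
        raise InputError(f"base concentration must be > 0, got {base}")

    if spec.name == "baseline" or (
        spec.terminal_target is None and spec.interim_reduction is None
    ):
        values = np.full(len(YEARS), base)
    elif spec.interim_reduction is not None:
        values = _policy_path(base, spec)
    else:
        policy = policy_spec or default_scenarios()["policy"]
        glide = _segment(BASE_YEAR, base, END_YEAR, min(spec.terminal_target, base))
        values = np.minimum(_policy_path(base, policy), glide)

    return ConcentrationTrajectory(
        city_id=city_id, scenario=spec.name, values=tuple(float(v) for v in values)
    )


def build_trajectories(
    cities: pd.DataFrame,
    specs: Optional[Mapping[str, ScenarioSpec]] = None,
) -> pd.DataFrame:
    """Long-format trajectory table for a city panel.

    ``cities`` needs columns ``city_id`` and ``pm25_2020``. Returns
    columns (city_id, scenario, year, pm25).
    """
    specs = dict(specs) if specs is not None else default_scenarios()
    if "baseline" not in specs:
        raise ConfigurationError("scenario set must include the baseline scenario")
    policy_spec = specs.get("policy", default_scenarios()["policy"])

    frames = []
    years = np.asarray(YEARS)
    for spec in specs.values():
        paths = np.stack(
            [
                build_trajectory(c, spec, city_id=str(i), policy_spec=policy_spec).as_array()
                for i, c in zip(cities["city_id"], cities["pm25_2020"])
            ]
        )
        frames.append(
            pd.DataFrame(
                {
                    "city_id": np.repeat(cities["city_id"].to_numpy(), len(years)),
                    "scenario": spec.name,
                    "year": np.tile(years, len(cities)),
                    "pm25": paths.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def validate_scenario_matrix(
    scenario_names: Iterable[str],
    ssp_labels: Iterable[str],
    known_scenarios: Optional[Sequence[str]] = None,
) -> list[tuple[str, str]]:
    """Cross-product run matrix of scenarios x SSP population variants.

    Deduplicates, validates labels, and forces the baseline scenario into
    every sweep (scenario benefits are always measured against it).
    """
    known = set(known_scenarios) if known_scenarios is not None else set(default_scenarios())
    scenarios = list(dict.fromkeys(scenario_names))
    ssps = list(dict.fromkeys(ssp_labels))
    if not scenarios:
        raise ConfigurationError("scenario set must not be empty")
    if not ssps:
        raise ConfigurationError("SSP set must not be empty")
    unknown = [s for s in scenarios if s not in known]
    if unknown:
        raise ConfigurationError(f"unknown scenario labels: {unknown}")
    bad_ssp = [s for s in ssps if s not in SSP_LABELS]
    if bad_ssp:
        raise ConfigurationError(f"unknown SSP labels: {bad_ssp}")
    if "baseline" not in scenarios:
        scenarios.insert(0, "baseline")
    return [(sc, ssp) for sc in scenarios for ssp in ssps]
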