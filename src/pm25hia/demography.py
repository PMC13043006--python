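"""Population projection under SSP variants and log-linear trend
projection of baseline rates and unit costs.

Populations are projected with national per-year multipliers per SSP
applied to every city's 2020 age-specific counts, so the age structure
is frozen at its 2020 shape for the whole horizon (a deliberate
simplification; see docs/methods.md).

Baseline mortality/admission rates and hospitalization unit costs are
extrapolated by ordinary least squares on log(value) versus calendar
year — a log-linear trend, which keeps projections positive. A history
with a single observation is carried forward flat.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .scenario_engine import BASE_YEAR, END_YEAR, YEARS


def fit_log_trend(years: Sequence[float], values: Sequence[float]) -> tuple[float, float, float]:
    """OLS fit of log(value) on year.

    Returns (intercept, slope, slope_se); the slope is the continuous
    annual growth rate. slope_se is NaN with fewer than 3 points (zero
    residual degrees of freedom).
    """
    t = np.asarray(years, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        raise InputError("empty history")
    if np.any(v <= 0):
        raise InputError("log-linear trend requires strictly positive history values")
    if t.size == 1:
        return float(np.log(v[0])), 0.0, float("nan")
    y = np.log(v)
    tbar = t.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * tbar)
    dof = t.size - 2
    if dof > 0:
        resid = y - (intercept + slope * t)
        slope_se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    else:
        slope_se = float("nan")
    return intercept, slope, slope_se


def _project_groups(
    history: pd.DataFrame,
    value_col: str,
    group_cols: list[str],
    target_years: Iterable[int],
) -> pd.DataFrame:
    if history.empty:
        raise InputError("empty history")
    target_years = list(target_years)
    out = []
    for keys, grp in history.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        intercept, slope, _ = fit_log_trend(grp["year"], grp[value_col])
        fitted = np.exp(intercept + slope * np.asarray(target_years, dtype=float))
        rec = pd.DataFrame({c: k for c, k in zip(group_cols, keys)}, index=range(len(target_years)))
        rec["year"] = target_years
        rec[value_col] = fitted
        out.append(rec)
    return pd.concat(out, ignore_index=True)


def project_baseline_rate(
    history: pd.DataFrame, target_years: Optional[Iterable[int]] = None
) -> pd.DataFrame:
    """Extrapolate baseline event rates to the modeled horizon.

    ``history`` is long-format (region, cause, age_group, year, rate)
    with at least one observed year per group. Each group gets its own
    log-linear trend; fitted (smoothed) values are returned for every
    target year, 2020-2030 by default.
    """
    return _project_groups(
        history, "rate", ["region", "cause", "age_group"], target_years or YEARS
    )


def project_unit_costs(
    history: pd.DataFrame, target_years: Optional[Iterable[int]] = None
) -> pd.DataFrame:
    """Extrapolate per-admission hospitalization costs (same contract as
    :func:`project_baseline_rate`, applied to (endpoint, year, cost_usd))."""
    return _project_groups(history, "cost_usd", ["endpoint"], target_years or YEARS)


def project_population(
    base_pop: pd.DataFrame,
    ssp_multipliers: pd.DataFrame,
    ssps: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Project 2020 age-specific city populations through 2030 per SSP.

    ``base_pop``: (city_id, age_group, persons_2020).
    ``ssp_multipliers``: (ssp, year, multiplier) with year-over-year
    national growth factors for 2021-2030; the base year is implicitly 1.
    Returns long format (city_id, ssp, year, age_group, persons); age
    shares within each city are preserved exactly across years.
    """
    if (ssp_multipliers["multiplier"] <= 0).any():
        raise InputError("population growth multipliers must be positive")
    ssps = list(ssps) if ssps is not None else sorted(ssp_multipliers["ssp"].unique())

    frames = []
    for ssp in ssps:
        rows = ssp_multipliers[ssp_multipliers["ssp"] == ssp].set_index("year")["multiplier"]
        missing = [y for y in YEARS[1:] if y not in rows.index]
        if rows.empty or missing:
            raise ConfigurationError(
                f"SSP multipliers missing for {ssp!r}" + (f" years {missing}" if missing else "")
            )
        cumulative = {BASE_YEAR: 1.0}
        acc = 1.0
        for year in YEARS[1:]:
            acc *= float(rows.loc[year])
            cumulative[year] = acc
        for year in YEARS:
            frame = base_pop.copy()
            frame = frame.rename(columns={"persons_2020": "persons"})
            frame["persons"] = frame["persons"] * cumulative[year]
            frame["ssp"] = ssp
            frame["year"] = year
            frames.append(frame[["city_id", "ssp", "year", "age_group", "persons"]])
    return pd.concat(frames, ignore_index=True)
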