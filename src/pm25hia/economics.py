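"""Monetization of averted burden: VSL for mortality, cost-of-illness
for morbidity, discounted to the base year.

Mortality benefit  = sum_y averted_deaths(y) * VSL * (1+r)^-(y-2020)
Morbidity benefit  = sum_{e,y} averted_admissions(e, y) * unit_cost(e, y)
                              * (1+r)^-(y-2020)

The VSL (default US $689,659) is held constant over time and uniform
across cities; the discount rate defaults to 5%/year. Discounting
applies to monetary values only — event counts are reported
undiscounted. Annual averages divide the period total by the number of
years (ten for 2021-2030).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import pandas as pd

from .errors import InputError

DEFAULT_VSL_USD = 689_659.0


@dataclass(frozen=True)
class EconomicParams:
    """Valuation constants: VSL (USD/statistical life), annual discount
    rate, and the base year money is discounted to."""

    vsl: float = DEFAULT_VSL_USD
    discount_rate: float = 0.05
    base_year: int = 2020
    currency_label: str = "USD"

    def __post_init__(self) -> None:
        if self.vsl <= 0:
            raise InputError(f"VSL must be > 0, got {self.vsl}")
        if not (0 <= self.discount_rate < 1):
            raise InputError(f"discount rate must be in [0, 1), got {self.discount_rate}")


@dataclass(frozen=True)
class EconomicResult:
    """Monetized benefits for one scenario cell."""

    scenario: str
    ssp: str
    geography: str
    period: str
    mortality_benefit: float
    morbidity_benefit: float
    per_capita: float

    @property
    def total_benefit(self) -> float:
        return self.mortality_benefit + self.morbidity_benefit


def discount_factor(year: int, params: EconomicParams) -> float:
    """(1 + r)^-(year - base_year); 1.0 in the base year."""
    if year < params.base_year:
        raise InputError(f"cannot discount year {year} before base year {params.base_year}")
    return (1.0 + params.discount_rate) ** (-(year - params.base_year))


def monetize_mortality(
    averted_deaths: Union[Mapping[int, float], pd.Series],
    params: EconomicParams,
) -> dict[str, float]:
    """Discounted VSL value of an averted-death stream keyed by year.

    Returns the period total and the annual average (total / n years).
    """
    series = pd.Series(averted_deaths, dtype=float)
    if (series < 0).any():
        raise InputError("averted deaths must be nonnegative")
    total = float(
        sum(v * params.vsl * discount_factor(int(y), params) for y, v in series.items())
    )
    n_years = max(len(series), 1)
    return {"total": total, "annual_average": total / n_years}


def monetize_morbidity(
    averted_admissions: pd.DataFrame,
    unit_costs: pd.DataFrame,
    params: EconomicParams,
) -> dict[str, float]:
    """Discounted cost-of-illness value of averted admissions.

    ``averted_admissions``: (endpoint, year, events); ``unit_costs``:
    (endpoint, year, cost_usd) covering every (endpoint, year) present.
    """
    costs = unit_costs.set_index(["endpoint", "year"])["cost_usd"]
    total = 0.0
    for _, row in averted_admissions.iterrows():
        key = (row["endpoint"], int(row["year"]))
        if key not in costs.index:
            raise InputError(f"unit cost missing for endpoint/year {key}")
        total += float(row["events"]) * float(costs.loc[key]) * discount_factor(
            int(row["year"]), params
        )
    n_years = max(averted_admissions["year"].nunique(), 1)
    return {"total": total, "annual_average": total / n_years}


def per_capita(total_benefit: float, person_years: float) -> float:
    """USD per person per year: benefit divided by person-years exposed."""
    if person_years <= 0:
        raise InputError(f"person-years must be > 0, got {person_years}")
    return total_benefit / person_years


def benefits_table(
    averted_mortality: pd.DataFrame,
    averted_admissions: pd.DataFrame,
    unit_costs: pd.DataFrame,
    person_years_by_geo: Mapping[str, float],
    params: EconomicParams,
    headline_cause: str = "NCD+LRI",
) -> pd.DataFrame:
    """Monetize per (scenario, ssp, geography).

    ``averted_mortality``: per-year rows (scenario, ssp, geography,
    cause, year, averted) — only the headline cause is monetized, since
    cause-specific deaths overlap with the combined category.
    ``averted_admissions``: (scenario, ssp, geography, endpoint, year,
    events). Returns one row per scenario x ssp x geography with
    mortality, morbidity and total benefits (period total and annual
    average) plus per-capita benefit per person-year.
    """
    mort = averted_mortality[averted_mortality["cause"] == headline_cause]
    records = []
    keys = ["scenario", "ssp", "geography"]
    all_keys = sorted(
        set(map(tuple, mort[keys].drop_duplicates().to_numpy()))
        | set(map(tuple, averted_admissions[keys].drop_duplicates().to_numpy()))
    )
    for sc, ssp, geo in all_keys:
        msub = mort[(mort["scenario"] == sc) & (mort["ssp"] == ssp) & (mort["geography"] == geo)]
        stream = dict(zip(msub["year"].astype(int), msub["averted"]))
        mres = monetize_mortality(stream, params) if stream else {"total": 0.0, "annual_average": 0.0}
        asub = averted_admissions[
            (averted_admissions["scenario"] == sc)
            & (averted_admissions["ssp"] == ssp)
            & (averted_admissions["geography"] == geo)
        ]
        if len(asub):
            ares = monetize_morbidity(
                asub.rename(columns={"averted": "events"})[["endpoint", "year", "events"]],
                unit_costs,
                params,
            )
        else:
            ares = {"total": 0.0, "annual_average": 0.0}
        total = mres["total"] + ares["total"]
        py = person_years_by_geo.get(geo)
        records.append(
            {
                "scenario": sc,
                "ssp": ssp,
                "geography": geo,
                "mortality_benefit_usd": mres["total"],
                "morbidity_benefit_usd": ares["total"],
                "total_benefit_usd": total,
                "annual_average_benefit_usd": mres["annual_average"] + ares["annual_average"],
                "per_capita_usd_per_year": per_capita(total, py) if py else float("nan"),
            }
        )
    return pd.DataFrame.from_records(records)
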