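"""Landscape carbon ledger and carbon-market (REDD+) valuation.

Bookkeeping of carbon stocks per area class (degraded / restored / retained)
across census and projection years: per-class carbon = area x carbon density,
period changes as absolute and percent deltas, annualised rates, conversion
to CO2-equivalent (1 t C = 3.67 t CO2e, the 44/12 molar ratio) and valuation
at a voluntary-market offset price.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

#: tonnes of CO2e per tonne of carbon (44/12)
DEFAULT_CO2E_FACTOR = 3.67

#: voluntary-market forestry offset price, USD per t CO2e (2018 average)
DEFAULT_PRICE_USD = 3.20


@dataclass(frozen=True)
class MarketParams:
    """Carbon-market accounting parameters."""

    co2e_factor: float = DEFAULT_CO2E_FACTOR
    price: float = DEFAULT_PRICE_USD
    area_ha: float = 1.0
    period_years: float = 1.0

    def __post_init__(self) -> None:
        if self.co2e_factor <= 0:
            raise ValueError("co2e_factor must be positive")
        if self.price < 0:
            raise ValueError("price must be non-negative")
        if self.area_ha <= 0:
            raise ValueError("area_ha must be positive")
        if self.period_years <= 0:
            raise ValueError("period_years must be positive")


@dataclass(frozen=True)
class PeriodChange:
    """Carbon-stock change over one period."""

    delta: float  # t C
    percent: float  # % of the starting stock
    annual_delta: float  # t C yr-1
    annual_percent: float  # % yr-1 of the starting stock


@dataclass
class CarbonLedger:
    """The full accounting object.

    ``stocks``  per-year, per-class area (ha) and carbon (t C), with a Total
                row per year.
    ``changes`` per consecutive-year period and class: delta t C, % change,
                CO2e of the delta and its market value.
    """

    stocks: pd.DataFrame
    changes: pd.DataFrame
    params: MarketParams


def class_carbon(
    areas: Mapping[str, float], carbon_density: Mapping[str, float]
) -> tuple[dict[str, float], float]:
    """Per-class carbon stock (t C) = area (ha) x density (t C ha-1), plus total."""
    if set(areas) != set(carbon_density):
        raise ValueError(
            f"class sets differ: {sorted(areas)} vs {sorted(carbon_density)}"
        )
    out = {}
    for c in areas:
        if areas[c] < 0 or carbon_density[c] < 0:
            raise ValueError(f"negative area or density for class {c!r}")
        out[c] = areas[c] * carbon_density[c]
    return out, sum(out.values())


def period_change(c_start: float, c_end: float, years: float) -> PeriodChange:
    """Absolute, percent and annualised carbon-stock change over a period."""
    if c_start <= 0:
        raise ValueError("c_start must be positive")
    if years <= 0:
        raise ValueError("years must be positive")
    delta = c_end - c_start
    return PeriodChange(
        delta=delta,
        percent=100.0 * delta / c_start,
        annual_delta=delta / years,
        annual_percent=100.0 * delta / years / c_start,
    )


def co2e(carbon: float, params: MarketParams | None = None) -> float:
    """CO2-equivalent (t CO2e) of a carbon stock (t C)."""
    if carbon < 0:
        raise ValueError("carbon must be non-negative")
    factor = (params or MarketParams()).co2e_factor
    return carbon * factor


def market_value(
    co2e_delta: float, params: MarketParams
) -> tuple[float, float, float]:
    """Offset value of a CO2e quantity: (total, per ha, per ha per year)."""
    total = co2e_delta * params.price
    per_ha = total / params.area_ha
    return total, per_ha, per_ha / params.period_years


def build_ledger(
    areas_by_year: Mapping[int, Mapping[str, float]],
    densities_by_year: Mapping[int, Mapping[str, float]],
    params: MarketParams,
) -> CarbonLedger:
    """Compose the stock and change tables of the carbon ledger.

    ``areas_by_year[year][cls]`` is the area (ha) and
    ``densities_by_year[year][cls]`` the carbon density (t C ha-1); the two
    mappings must cover the same years and classes.  Change rows are built
    between consecutive years (sorted), with the period length from the year
    difference; CO2e and valuation apply to the Total row of each period.
    """
    years = sorted(areas_by_year)
    if sorted(densities_by_year) != years:
        raise ValueError("areas_by_year and densities_by_year must cover the same years")
    if not years:
        raise ValueError("need at least one year")
    classes = sorted(areas_by_year[years[0]])

    stock_rows = []
    carbon_by_year: dict[int, dict[str, float]] = {}
    for y in years:
        if sorted(areas_by_year[y]) != classes or sorted(densities_by_year[y]) != classes:
            raise ValueError(f"year {y}: class set differs from {classes}")
        per_class, total = class_carbon(areas_by_year[y], densities_by_year[y])
        carbon_by_year[y] = per_class
        for c in classes:
            stock_rows.append(
                {
                    "year": y,
                    "area_class": c,
                    "area_ha": areas_by_year[y][c],
                    "carbon_tC": per_class[c],
                }
            )
        stock_rows.append(
            {
                "year": y,
                "area_class": "Total",
                "area_ha": sum(areas_by_year[y].values()),
                "carbon_tC": total,
            }
        )
    stocks = pd.DataFrame(stock_rows)

    change_rows = []
    for y0, y1 in zip(years, years[1:]):
        span = float(y1 - y0)
        for c in classes + ["Total"]:
            c0 = (
                sum(carbon_by_year[y0].values())
                if c == "Total"
                else carbon_by_year[y0][c]
            )
            c1 = (
                sum(carbon_by_year[y1].values())
                if c == "Total"
                else carbon_by_year[y1][c]
            )
            ch = period_change(c0, c1, span)
            delta_co2e = ch.delta * params.co2e_factor
            value, value_ha, value_ha_yr = market_value(
                delta_co2e,
                MarketParams(
                    co2e_factor=params.co2e_factor,
                    price=params.price,
                    area_ha=params.area_ha,
                    period_years=span,
                ),
            )
            change_rows.append(
                {
                    "period": f"{y0}-{y1}",
                    "area_class": c,
                    "delta_tC": ch.delta,
                    "percent": ch.percent,
                    "annual_delta_tC": ch.annual_delta,
                    "annual_percent": ch.annual_percent,
                    "delta_tCO2e": delta_co2e,
                    "value": value,
                    "value_per_ha": value_ha,
                    "value_per_ha_per_year": value_ha_yr,
                }
            )
    changes = pd.DataFrame(change_rows)
    return CarbonLedger(stocks=stocks, changes=changes, params=params)


def densities_from_stocks(
    areas: Mapping[str, float], carbon: Mapping[str, float]
) -> dict[str, float]:
    """Back-compute per-class carbon densities (t C ha-1) from stocks and areas."""
    if set(areas) != set(carbon):
        raise ValueError("class sets differ")
    out = {}
    for c in areas:
        if areas[c] <= 0:
            raise ValueError(f"class {c!r} has non-positive area")
        out[c] = carbon[c] / areas[c]
    return out
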