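"""Stratified fertility rates, historic extrapolation and dampening.

Fertility rates FR_{y,a,s,r} are live births per person-year in each year,
parental age band, sex and race/ethnicity stratum, computed as the ratio of
natality to population counts.  Because population denominators stratified
by race are unavailable before the first observed year, earlier years reuse
the first observed year's rates (historic extrapolation); a sensitivity mode
accepts observed earlier rates instead.

The dampened-fertility scenarios model the possibility that fertility of
individuals declines in the years preceding their death: rates taper along
a cumulative-logistic curve from the population level at the onset horizon
down to a floor (zero or half) in the year of death.
"""

from __future__ import annotations

import logging

from typing import Literal

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, EstimationError

logger = logging.getLogger(__name__)

Scenario = Literal["none", "zero@death", "half@death"]
_FLOORS = {"zero@death": 0.0, "half@death": 0.5}


def compute_fertility(births: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Fertility rate table: rate = births / population per stratum.

    Strata present in the natality table must be present in the population
    table.  A zero denominator with a positive numerator is an estimation
    error; with a zero numerator the rate is 0 with a warning.
    """
    keys = [c for c in ("year", "age_band", "sex", "race_ethnicity", "state") if c in births.columns]
    pop_keys = [c for c in keys if c in population.columns]
    if pop_keys != keys:
        raise AlignmentError(f"population table lacks strata columns {set(keys) - set(pop_keys)}")
    merged = births.merge(
        population[keys + ["count"]].rename(columns={"count": "pop"}),
        on=keys,
        how="left",
    )
    if merged["pop"].isna().any():
        missing = merged.loc[merged["pop"].isna(), keys].iloc[0].to_dict()
        raise AlignmentError(f"population stratum missing for {missing}")
    zero_pop = merged["pop"] == 0
    if (zero_pop & (merged["count"] > 0)).any():
        raise EstimationError("births reported in a stratum with zero population")
    if zero_pop.any():
        logger.warning("%d strata have zero population and zero births; rate set to 0", int(zero_pop.sum()))
    merged["rate"] = np.where(zero_pop, 0.0, merged["count"] / merged["pop"].where(~zero_pop, 1))
    return merged[keys + ["rate"]]


def extend_historic(
    rates: pd.DataFrame,
    reference_year: int,
    earliest_year: int,
) -> pd.DataFrame:
    """Extend a fertility-rate table backward to ``earliest_year``.

    Years before ``reference_year`` that are absent from ``rates`` receive
    the ``reference_year`` rates (the constant-before-reference assumption);
    years already observed — including earlier observed rates supplied in a
    sensitivity mode — take precedence and are returned unchanged.
    """
    if earliest_year >= reference_year:
        return rates.reset_index(drop=True)
    ref = rates[rates["year"] == reference_year]
    if ref.empty:
        raise EstimationError(f"reference year {reference_year} absent from rates")
    observed_years = set(rates["year"].unique())
    blocks = [rates]
    for year in range(earliest_year, reference_year):
        if year in observed_years:
            continue
        filled = ref.copy()
        filled["year"] = year
        blocks.append(filled)
    out = pd.concat(blocks, ignore_index=True)
    return out.sort_values([c for c in ("year", "sex", "race_ethnicity", "age_band") if c in out.columns]).reset_index(
        drop=True
    )


class FertilityLookup:
    """Queryable fertility rates with range checking.

    Wraps an extended rate table; queries before the earliest supported year
    raise an estimation error rather than silently extrapolating.
    """

    def __init__(self, rates: pd.DataFrame):
        self.rates = rates
        self.earliest = int(rates["year"].min())
        keys = [c for c in ("year", "sex", "race_ethnicity", "age_band") if c in rates.columns]
        self._table = rates.set_index(keys)["rate"].to_dict()

    def rate(self, year: int, sex: str, race: str, band: str) -> float:
        if year < self.earliest:
            raise EstimationError(f"fertility query for {year} precedes earliest supported year {self.earliest}")
        return float(self._table.get((year, sex, race, band), 0.0))


def dampen_fertility(
    rate: float | np.ndarray,
    years_before_death: float | np.ndarray,
    scenario: Scenario = "none",
    onset: int = 0,
    scale: float = 0.5,
) -> float | np.ndarray:
    """Dampen a fertility rate as death approaches (sensitivity scenarios).

    The adjustment is a cumulative-logistic taper in years-to-death: the
    factor equals the scenario floor (0 or 0.5) in the year of death, rises
    along a logistic curve with the given scale (years) over the onset
    horizon, and is exactly 1 at and beyond ``onset`` years before death.
    Scenario ``none`` is the identity.  Onsets of 0, 1 and 3 years mirror
    the study's sensitivity settings.
    """
    if scenario == "none":
        return rate
    if scenario not in _FLOORS:
        raise ConfigurationError(f"unknown dampening scenario {scenario!r}")
    if onset < 0:
        raise ConfigurationError("onset must be non-negative")
    floor = _FLOORS[scenario]
    t = np.asarray(years_before_death, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("years_before_death must be non-negative")

    if onset == 0:
        factor = np.where(t <= 0, floor, 1.0)
    else:
        # Logistic centred mid-horizon, renormalized so the endpoints are
        # exact: factor(0) = floor, factor(t >= onset) = 1.
        def g(x: np.ndarray) -> np.ndarray:
            return 1.0 / (1.0 + np.exp(-(x - onset / 2.0) / scale))

        g0, g1 = g(np.array(0.0)), g(np.array(float(onset)))
        frac = np.clip((g(t) - g0) / (g1 - g0), 0.0, 1.0)
        factor = floor + (1.0 - floor) * frac
        factor = np.where(t >= onset, 1.0, factor)
    out = np.asarray(rate, dtype=float) * factor
    if np.isscalar(rate) or np.ndim(rate) == 0:
        return float(out) if np.ndim(out) == 0 else float(out.item())
    return out


def compute_mortality_rate(deaths: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Crude mortality rate per stratum, the same ratio operator as
    :func:`compute_fertility` applied to all-cause death counts."""
    keys = [c for c in ("year", "age_band", "sex", "race_ethnicity", "state") if c in deaths.columns]
    totals = deaths.groupby(keys, as_index=False, observed=True)["count"].sum()
    return compute_fertility(totals, population)
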