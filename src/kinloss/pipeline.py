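"""End-to-end estimation flows over validated input tables.

``estimate_national`` wires the full national pipeline: fertility rates with
historic extrapolation, expected children per decedent, band hazards,
incidence with double-loss corrections, survival-adjusted prevalence, and
grandparent-caregiver loss with de-duplication.  ``estimate_state`` runs the
race-unstratified state flow with suppression imputation, national
rescaling of mortality, and national correction factors on incidence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bands, grandparents, orphanhood, states
from .errors import EstimationError
from .fertility import FertilityLookup, compute_fertility, extend_historic
from .grandparents import DedupParams

PREVALENCE_LOOKBACK = 17
HAZARD_LOOKBACK = 16


def split_child_strata(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a mixed-granularity table into adult-band and child-age rows."""
    is_child = df["age_band"].map(bands.is_child_band)
    return df[~is_child].reset_index(drop=True), df[is_child].reset_index(drop=True)


def population_for_natality(population: pd.DataFrame, sex: str) -> pd.DataFrame:
    """Aggregate 5-year adult population bands to the natal band scheme.

    Mother bands coincide with 5-year bands; the father band 55-77 pools the
    5-year bands 55-59 through 75-79 (the 78-79 overhang is retained, a
    conventional approximation at ages with near-zero fertility).
    """
    natal = bands.MOTHER_BANDS if sex == "female" else bands.FATHER_BANDS
    pop = population[population["sex"] == sex].copy()

    def to_natal(band: str) -> str | None:
        lo, _ = bands.parse_band(band)
        return bands.band_for_age(lo, natal)

    pop["age_band"] = pop["age_band"].map(to_natal)
    pop = pop.dropna(subset=["age_band"])
    keys = [c for c in ("year", "age_band", "sex", "race_ethnicity", "state") if c in pop.columns]
    return pop.groupby(keys, as_index=False, observed=True)["count"].sum()


def fertility_rates(natality: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """Sex-specific fertility rates on the natal band scheme."""
    blocks = []
    for sex in bands.SEXES:
        births = natality[natality["sex"] == sex]
        if births.empty:
            continue
        pop = population_for_natality(population, sex)
        blocks.append(compute_fertility(births, pop))
    return pd.concat(blocks, ignore_index=True)


def _natality_age_weights(natality: pd.DataFrame) -> pd.DataFrame:
    """Parent age composition (birth shares per band) used to weight
    parental mortality rates in the caregiver de-duplication step."""
    keys = [c for c in ("year", "sex", "race_ethnicity", "state") if c in natality.columns]
    out = natality.copy()
    totals = out.groupby(keys, observed=True)["count"].transform("sum")
    out["weight"] = out["count"] / totals.where(totals > 0, 1)
    out = out[totals > 0]
    return out[keys + ["age_band", "weight"]]


def _natal_band_mortality_rates(deaths: pd.DataFrame, population: pd.DataFrame) -> pd.DataFrame:
    """All-cause death rates aggregated to the natal band scheme."""
    blocks = []
    for sex in bands.SEXES:
        d = deaths[deaths["sex"] == sex].copy()
        natal = bands.MOTHER_BANDS if sex == "female" else bands.FATHER_BANDS
        d["age_band"] = d["age_band"].map(lambda b: bands.band_for_age(bands.parse_band(b)[0], natal))
        d = d.dropna(subset=["age_band"])
        keys = [c for c in ("year", "age_band", "sex", "race_ethnicity", "state") if c in d.columns]
        dsum = d.groupby(keys, as_index=False, observed=True)["count"].sum()
        pop = population_for_natality(population, sex)
        merged = pop.rename(columns={"count": "pop"}).merge(dsum, on=keys, how="left")
        merged["count"] = merged["count"].fillna(0.0)
        merged["rate"] = merged["count"] / merged["pop"].where(merged["pop"] > 0, 1)
        blocks.append(merged[keys + ["rate"]])
    return pd.concat(blocks, ignore_index=True)


def estimate_national(
    tables: dict[str, pd.DataFrame],
    incidence_years: list[int],
    prevalence_years: list[int],
    dedup_params: DedupParams | None = None,
    composition_mode: str = "cause_specific",
) -> dict[str, pd.DataFrame]:
    """Run the full national pipeline on validated input tables.

    ``tables`` must provide mortality, natality, population, child_survival
    and caregiver tables.  Returns the intermediate and final tables:
    fertility rates, expected children, hazards, incidence components,
    combined and by-sex incidence, orphanhood prevalence, grandparent-loss
    and combined caregiver-loss incidence and prevalence.
    """
    for name in ("mortality", "natality", "population", "child_survival", "caregiver"):
        if name not in tables:
            raise EstimationError(f"missing input table: {name}")
    mortality, natality = tables["mortality"], tables["natality"]
    population, survival = tables["population"], tables["child_survival"]

    adult_deaths, child_deaths = split_child_strata(mortality)
    adult_pop, child_pop = split_child_strata(population)

    earliest_fert = min(incidence_years) - PREVALENCE_LOOKBACK
    rates = fertility_rates(natality, adult_pop)
    reference_year = int(rates["year"].min())
    rates = extend_historic(rates, reference_year, earliest_fert)
    fert = FertilityLookup(rates)

    C = orphanhood.expected_children(fert, survival, incidence_years)
    hazards = orphanhood.mortality_hazard(adult_deaths, adult_pop, strict=False)

    # Child hazards by race (single-age strata, n = 1).
    ch_deaths = child_deaths.groupby(
        [c for c in ("year", "age_band", "race_ethnicity") if c in child_deaths.columns],
        as_index=False,
        observed=True,
    )["count"].sum()
    ch_pop = child_pop.groupby(
        [c for c in ("year", "age_band", "race_ethnicity") if c in child_pop.columns],
        as_index=False,
        observed=True,
    )["count"].sum()
    child_hazards = ch_pop.rename(columns={"count": "pop"}).merge(
        ch_deaths, on=["year", "age_band", "race_ethnicity"], how="left"
    )
    child_hazards["count"] = child_hazards["count"].fillna(0.0)
    child_hazards["hazard"] = (child_hazards["count"] / child_hazards["pop"].where(child_hazards["pop"] > 0, 1)).clip(0, 1)

    deaths_inc = adult_deaths[adult_deaths["year"].isin(incidence_years)]
    components = orphanhood.incidence_components(C, deaths_inc, hazards)
    new_combined, new_by_sex = orphanhood.combine_incidence(components)

    lifetime = orphanhood.accumulate_prevalence(
        new_combined, child_hazards, prevalence_years, computed_years=incidence_years
    )
    lifetime_by_sex = orphanhood.accumulate_prevalence(
        new_by_sex, child_hazards, prevalence_years, computed_years=incidence_years
    )

    # Grandparent caregiver loss.
    props = grandparents.caregiver_proportions(tables["caregiver"])
    G = grandparents.grandparent_incidence(props, deaths_inc)
    composition = grandparents.orphanhood_age_composition(components, mode=composition_mode)
    G_by_age = grandparents.disaggregate_child_age(G, composition)

    rate_table = _natal_band_mortality_rates(adult_deaths, adult_pop)
    weights = _natality_age_weights(natality[natality["year"].isin(incidence_years)])
    parent_h = grandparents.parent_hazard_aggregate(rate_table, weights)

    G_dedup = grandparents.dedup_caregiver(G_by_age, parent_h, dedup_params)
    L_new = grandparents.combine_caregiver_incidence(new_by_sex, G_dedup)
    L_lifetime = grandparents.caregiver_prevalence(
        lifetime_by_sex, G_dedup, child_hazards, prevalence_years
    )

    return {
        "fertility": rates,
        "expected_children": C,
        "hazards": hazards,
        "child_hazards": child_hazards[["year", "age_band", "race_ethnicity", "hazard"]],
        "components": components,
        "new_combined": new_combined,
        "new_by_sex": new_by_sex,
        "lifetime": lifetime,
        "lifetime_by_sex": lifetime_by_sex,
        "caregiver_proportions": props,
        "G": G,
        "G_dedup": G_dedup,
        "L_new": L_new,
        "L_lifetime": L_lifetime,
    }


def _aggregate_race(df: pd.DataFrame, label: str = "all") -> pd.DataFrame:
    out = df.copy()
    out["race_ethnicity"] = label
    keys = [c for c in out.columns if c not in ("count", "suppressed")]
    agg = out.groupby(keys, as_index=False, observed=True, dropna=False)["count"].sum()
    return agg


def prepare_state_inputs(
    tables: dict[str, pd.DataFrame],
    suppress: bool = True,
    threshold: int = states.SUPPRESSION_THRESHOLD,
) -> dict[str, pd.DataFrame]:
    """Collapse race stratification and apply small-count suppression to
    per-state tables, mirroring the disclosure rules of public state
    tabulations.

    Race is collapsed to a single ``all`` category (state estimation runs
    unstratified); adult mortality cells below the threshold are masked as
    suppressed.  The caregiver table keeps its sex split with the race
    share fixed at 1.
    """
    out: dict[str, pd.DataFrame] = {}
    for name in ("mortality", "natality", "population"):
        out[name] = _aggregate_race(tables[name])
    if suppress:
        adult, child = split_child_strata(out["mortality"])
        adult = states.suppress_small_counts(adult, threshold)
        out["mortality"] = pd.concat([adult, child], ignore_index=True)
    out["child_survival"] = tables["child_survival"]
    cg = tables["caregiver"].copy()
    keys = [c for c in ("year", "sex", "state") if c in cg.columns]
    cg = cg.groupby(keys, as_index=False, observed=True).first()
    cg["race_ethnicity"] = "all"
    cg["p_coreside_race"] = 1.0
    out["caregiver"] = cg
    return out


def estimate_state(
    state_tables: dict[str, pd.DataFrame],
    national_tables: dict[str, pd.DataFrame],
    incidence_years: list[int],
    prevalence_years: list[int],
    impute_mode: str = "state",
) -> dict[str, pd.DataFrame]:
    """State-level orphanhood with suppression adjustment and correction.

    State inputs carry a ``state`` column and no race stratification (race
    is collapsed to a single category, as public state tabulations
    suppress small race-stratified counts).  Suppressed mortality cells are
    imputed, state counts rescaled to national totals (eta), the national
    pipeline machinery runs per state, and summed state incidence is
    aligned to the national estimate (nu).
    """
    national = estimate_national(national_tables, incidence_years, prevalence_years)

    mortality = states.impute_suppressed(state_tables["mortality"], mode=impute_mode)
    adult_state, child_state = split_child_strata(mortality)
    nat_adult, _ = split_child_strata(_aggregate_race(national_tables["mortality"]))
    adjusted, eta_audit = states.rescale_to_national(adult_state, nat_adult)

    state_pop = state_tables["population"]
    state_nat = state_tables["natality"]
    results = []
    for state in sorted(adjusted["state"].unique()):
        tab = {
            "mortality": pd.concat(
                [
                    adjusted[adjusted["state"] == state],
                    child_state[child_state["state"] == state],
                ],
                ignore_index=True,
            ).drop(columns="state"),
            "natality": state_nat[state_nat["state"] == state].drop(columns="state"),
            "population": state_pop[state_pop["state"] == state].drop(columns="state"),
            "child_survival": state_tables["child_survival"],
            "caregiver": state_tables["caregiver"][
                state_tables["caregiver"]["state"] == state
            ].drop(columns="state"),
        }
        res = estimate_national(tab, incidence_years, prevalence_years)
        for key in ("new_combined", "new_by_sex", "components", "lifetime", "G", "L_new"):
            res[key] = res[key].assign(state=state)
        results.append(res)

    state_new_by_sex = pd.concat([r["new_by_sex"] for r in results], ignore_index=True)
    corrected, nu_audit = states.state_correction(state_new_by_sex, national["new_by_sex"])

    return {
        "national": national,
        "eta_audit": eta_audit,
        "nu_audit": nu_audit,
        "state_new_by_sex": corrected,
        "state_new_combined": pd.concat([r["new_combined"] for r in results], ignore_index=True),
        "state_lifetime": pd.concat([r["lifetime"] for r in results], ignore_index=True),
        "state_G": pd.concat([r["G"] for r in results], ignore_index=True),
        "per_state": results,
    }
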