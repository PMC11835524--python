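"""Grandparent-caregiver loss and combined caregiver loss.

Grandparent-caregiver loss is estimated from survey co-residence
proportions: the sex-specific share of adults aged 30+ living with
grandchildren, a race share, the proportion providing most of the
grandchildren's basic needs, and the skip-generation share among those.
Their products give the probability that a decedent aged 30+ was a
caregiver of each type; each caregiver death leaves a minimum of one child
behind.  Primary caregivers are the skip-generation and
most-responsible-not-skip-generation types; secondary caregivers co-reside
and head the household without providing most basic needs.

Combined caregiver loss de-duplicates children counted under both parental
and grandparent loss: fixed proportions of grandparent-cared children whose
parents had already died are removed, and a half-year exposure to parental
mortality after the survey reference point is discounted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bands
from .errors import ConfigurationError, EstimationError
from .orphanhood import ChildHazardIndex, MAX_CHILD_AGE

logger = logging.getLogger(__name__)

CAREGIVER_TYPES = ("skip_gen", "most_responsible_not_sg", "co_reside_not_mr")
#: Minimum parental age band boundary for grandparent caregivers.
GRANDPARENT_MIN_AGE = 30


@dataclass(frozen=True)
class DedupParams:
    """De-duplication constants for combined caregiver loss.

    ``p_skip_gen_parent_died``: share of skip-generation grandchildren whose
    parent(s) had already died (most skip-generation care arises from causes
    other than parental death).  ``p_other_parent_died``: among grandchildren
    co-residing with one parent, the share whose other parent had died.
    ``p_both_parents_present``: share of non-skip-generation grandchildren
    co-residing with both parents.  ``exposure_fraction``: average fraction
    of the year remaining after the survey reference point during which a
    parent may still die (6/12).
    """

    p_skip_gen_parent_died: float = 0.11
    p_other_parent_died: float = 0.11
    p_both_parents_present: float = 0.70
    exposure_fraction: float = 0.5

    def __post_init__(self):
        for name in ("p_skip_gen_parent_died", "p_other_parent_died", "p_both_parents_present", "exposure_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")


def caregiver_proportions(acs: pd.DataFrame) -> pd.DataFrame:
    """Derive caregiver-type proportions per (year, sex, race).

    gamma_skip_gen = gamma_coreside x p_coreside_race x p_most_responsible x
    q_skip_gen; the most-responsible-not-skip-generation and
    co-reside-not-most-responsible types use the complementary factors, so
    the three derived proportions sum exactly to gamma_coreside x
    p_coreside_race.  Years before the earliest survey year (2010 in the
    study design) reuse that year's values.
    """
    for col in ("gamma_coreside", "p_coreside_race", "p_most_responsible", "q_skip_gen"):
        if col not in acs.columns:
            raise ConfigurationError(f"ACS-style table missing column {col}")
        if ((acs[col] < 0) | (acs[col] > 1)).any():
            raise ConfigurationError(f"proportion {col} outside [0, 1]")
    out = acs.copy()
    base = out["gamma_coreside"] * out["p_coreside_race"]
    out["gamma_skip_gen"] = base * out["p_most_responsible"] * out["q_skip_gen"]
    out["gamma_most_responsible_not_sg"] = base * out["p_most_responsible"] * (1 - out["q_skip_gen"])
    out["gamma_co_reside_not_mr"] = base * (1 - out["p_most_responsible"])
    return out


def proportions_for_year(props: pd.DataFrame, year: int) -> pd.DataFrame:
    """Proportion rows applicable to ``year``; years before the earliest
    survey year fall back to the earliest year's values."""
    earliest = int(props["year"].min())
    use_year = year if year in set(props["year"]) else (earliest if year < earliest else None)
    if use_year is None:
        raise EstimationError(f"no caregiver proportions for year {year}")
    rows = props[props["year"] == use_year].copy()
    rows["year"] = year
    return rows


def grandparent_incidence(props: pd.DataFrame, deaths: pd.DataFrame) -> pd.DataFrame:
    """Children newly losing a grandparent caregiver: G^x = gamma^x x
    (deaths among adults 30+), per (year, sex, race, cause).

    Each caregiver death leaves a minimum of one child behind, so this is a
    lower bound.  Also returns the primary (skip-gen + most-responsible) and
    secondary (co-reside-not-mr) aggregations.
    """
    d = deaths.copy()
    d["_lo"] = d["age_band"].map(lambda b: bands.parse_band(b)[0])
    d30 = d[d["_lo"] >= GRANDPARENT_MIN_AGE]
    if d30.empty:
        raise EstimationError("deaths table has no age bands at 30+")
    keys = [c for c in ("year", "sex", "race_ethnicity", "state", "cause") if c in d30.columns]
    totals = d30.groupby(keys, as_index=False, observed=True)["count"].sum()

    prop_blocks = []
    for year in sorted(totals["year"].unique()):
        prop_blocks.append(proportions_for_year(props, int(year)))
    props_y = pd.concat(prop_blocks, ignore_index=True)
    join_keys = [c for c in ("year", "sex", "race_ethnicity", "state") if c in totals.columns and c in props_y.columns]
    merged = totals.merge(props_y, on=join_keys, how="left")
    if merged["gamma_skip_gen"].isna().any():
        raise EstimationError("caregiver proportions missing for some death strata")
    for x in CAREGIVER_TYPES:
        merged[f"G_{x}"] = merged[f"gamma_{x}"] * merged["count"]
    merged["G_primary"] = merged["G_skip_gen"] + merged["G_most_responsible_not_sg"]
    merged["G_secondary"] = merged["G_co_reside_not_mr"]
    cols = keys + [f"G_{x}" for x in CAREGIVER_TYPES] + ["G_primary", "G_secondary"]
    return merged[cols]


def orphanhood_age_composition(
    new_by_sex_band: pd.DataFrame,
    mode: str = "cause_specific",
) -> pd.DataFrame:
    """Age composition of children losing parents aged 30+, used as a proxy
    for the age composition of grandchildren losing caregivers.

    ``new_by_sex_band`` carries orphanhood incidence by (year, age_band,
    sex, race, child_age, cause) components (death_of_parent - previous).
    The numerator pools over years and bands at 30+; mode ``cause_specific``
    keeps causes separate, mode ``all_cause`` pools the numerator over
    causes before weighting.  Strata whose pooled numerator is all zero
    receive uniform weights with a warning.
    """
    if mode not in ("cause_specific", "all_cause"):
        raise ConfigurationError(f"unknown composition mode {mode!r}")
    df = new_by_sex_band.copy()
    df["_lo"] = df["age_band"].map(lambda b: bands.parse_band(b)[0])
    df = df[df["_lo"] >= GRANDPARENT_MIN_AGE]
    df["value"] = df["death_of_parent"] - df["previous"]
    group = [c for c in ("sex", "race_ethnicity", "state") if c in df.columns]
    if mode == "cause_specific":
        group = group + ["cause"]
    pooled = df.groupby(group + ["child_age"], as_index=False, observed=True)["value"].sum()
    totals = pooled.groupby(group, observed=True)["value"].transform("sum")
    pooled["weight"] = np.where(totals > 0, pooled["value"] / totals.where(totals > 0, 1), np.nan)
    n_zero = pooled["weight"].isna().sum()
    if n_zero:
        logger.warning("uniform age weights for %d strata with all-zero composition", n_zero)
        pooled["weight"] = pooled["weight"].fillna(1.0 / (MAX_CHILD_AGE + 1))
    return pooled[group + ["child_age", "weight"]]


def disaggregate_child_age(
    G: pd.DataFrame,
    composition: pd.DataFrame,
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Split caregiver-loss counts over child ages 0-17 by composition
    weights (or externally supplied survey weights); conserves totals."""
    w = composition if weights is None else weights
    join = [c for c in ("sex", "race_ethnicity", "state", "cause") if c in G.columns and c in w.columns]
    merged = G.merge(w, on=join, how="left")
    if merged["weight"].isna().any():
        # Strata without composition info: uniform split.
        logger.warning("uniform age weights for strata lacking composition")
        fallback = G.merge(w[join].drop_duplicates(), on=join, how="left", indicator=True)
        merged = merged.dropna(subset=["weight"])
        miss = fallback[fallback["_merge"] == "left_only"].drop(columns="_merge")
        if not miss.empty:
            uni = miss.loc[miss.index.repeat(MAX_CHILD_AGE + 1)].copy()
            uni["child_age"] = np.tile(np.arange(MAX_CHILD_AGE + 1), len(miss))
            uni["weight"] = 1.0 / (MAX_CHILD_AGE + 1)
            merged = pd.concat([merged, uni], ignore_index=True)
    for col in [c for c in merged.columns if c.startswith("G_")]:
        merged[col] = merged[col] * merged["weight"]
    return merged.drop(columns=["weight"])


def parent_hazard_aggregate(rates: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Parent-age-weighted mortality rate h^parent_{y,s,r}.

    ``rates`` carries (year, age_band, sex, race, rate); ``weights`` carries
    (age_band [, sex, race_ethnicity, year], weight) summing to 1 per
    stratum.  Returns the weighted mean rate per (year, sex, race).
    """
    join = [c for c in ("year", "age_band", "sex", "race_ethnicity") if c in weights.columns]
    merged = rates.merge(weights, on=join, how="inner")
    group = [c for c in ("year", "sex", "race_ethnicity", "state") if c in merged.columns]
    wsum = merged.groupby(group, observed=True)["weight"].sum()
    if not np.allclose(wsum, 1.0, atol=1e-9):
        raise ConfigurationError("parent age weights must sum to 1 per stratum")
    merged["_wr"] = merged["rate"] * merged["weight"]
    out = merged.groupby(group, as_index=False, observed=True)["_wr"].sum()
    return out.rename(columns={"_wr": "h_parent"})


def dedup_caregiver(
    G: pd.DataFrame,
    parent_hazards: pd.DataFrame,
    params: DedupParams | None = None,
) -> pd.DataFrame:
    """De-duplicated grandparent-caregiver loss G^de-dup.

    Skip-generation losses are reduced by the share whose parents had
    already died; other losses by the share whose sole co-residing parent's
    partner had died; both are further discounted for the chance that a
    parent died in the half-year after the survey reference point, using the
    parent-age-weighted hazards h^parent for each sex.
    """
    params = params or DedupParams()
    hp = parent_hazards.pivot_table(
        index=[c for c in ("year", "race_ethnicity", "state") if c in parent_hazards.columns],
        columns="sex",
        values="h_parent",
    ).rename(columns={"female": "h_F", "male": "h_M"}).reset_index()
    join = [c for c in ("year", "race_ethnicity", "state") if c in G.columns and c in hp.columns]
    merged = G.merge(hp, on=join, how="left")
    if merged[["h_F", "h_M"]].isna().any().any():
        raise EstimationError("parent hazards missing for some caregiver strata")
    either = merged["h_M"] + merged["h_F"] - merged["h_M"] * merged["h_F"]
    exposure = 1.0 - either * params.exposure_fraction
    skip = merged["G_skip_gen"] * (1.0 - params.p_skip_gen_parent_died) * exposure
    other = (
        (merged["G_most_responsible_not_sg"] + merged["G_co_reside_not_mr"])
        * (
            params.p_both_parents_present
            + (1.0 - params.p_both_parents_present) * (1.0 - params.p_other_parent_died)
        )
        * exposure
    )
    other_factor = (
        params.p_both_parents_present
        + (1.0 - params.p_both_parents_present) * (1.0 - params.p_other_parent_died)
    ) * exposure
    out = merged.drop(columns=["h_F", "h_M"])
    out["G_dedup"] = skip + other
    # Primary/secondary split of the de-duplicated counts, for reporting.
    out["G_dedup_primary"] = skip + merged["G_most_responsible_not_sg"] * other_factor
    out["G_dedup_secondary"] = merged["G_co_reside_not_mr"] * other_factor
    return out


def combine_caregiver_incidence(O_new: pd.DataFrame, G_dedup: pd.DataFrame) -> pd.DataFrame:
    """Total caregiver-loss incidence L^new = O^new + G^de-dup per stratum."""
    keys = [c for c in ("year", "sex", "race_ethnicity", "state", "child_age", "cause") if c in O_new.columns and c in G_dedup.columns]
    merged = O_new.rename(columns={"new": "O_new"}).merge(
        G_dedup[keys + ["G_dedup"]], on=keys, how="outer"
    )
    merged[["O_new", "G_dedup"]] = merged[["O_new", "G_dedup"]].fillna(0.0)
    merged["L_new"] = merged["O_new"] + merged["G_dedup"]
    return merged


def caregiver_prevalence(
    O_lifetime: pd.DataFrame,
    G_dedup_by_age: pd.DataFrame,
    child_hazards: pd.DataFrame,
    years: list[int],
) -> pd.DataFrame:
    """Combined caregiver-loss prevalence L^lifetime.

    L^lifetime_{y,b} = O^lifetime_{y,b} + sum_{i=0..b} G^de-dup_{y-i, b-i}
    x prod_{j=0..i} (1 - 1h_{y-j, b-j}).  Unlike orphanhood prevalence the
    survival product starts at j = 0, because the cross-sectional
    grandparent contributions do not already condition on the child
    surviving the year of loss; implemented as specified.
    """
    hz = ChildHazardIndex(child_hazards)
    group_cols = [c for c in ("sex", "race_ethnicity", "state", "cause") if c in G_dedup_by_age.columns]
    sum_keys = ["year"] + group_cols + ["child_age"]
    value_cols = [c for c in ("G_dedup", "G_dedup_primary", "G_dedup_secondary") if c in G_dedup_by_age.columns]
    flat = G_dedup_by_age.groupby(sum_keys, as_index=False, observed=True)[value_cols].sum()

    have_years = set(flat["year"].unique())
    needed = {y - i for y in years for i in range(MAX_CHILD_AGE + 1)}
    missing = needed - have_years
    if missing:
        raise EstimationError(f"G_dedup history missing years {sorted(missing)}")
    tables = {vc: flat.set_index(sum_keys)[vc].to_dict() for vc in value_cols}

    records = []
    for grp in (flat[group_cols].drop_duplicates().itertuples(index=False) if group_cols else [()]):
        grp = tuple(grp)
        race = grp[group_cols.index("race_ethnicity")] if "race_ethnicity" in group_cols else None
        for y in years:
            for b in range(MAX_CHILD_AGE + 1):
                totals = {vc: 0.0 for vc in value_cols}
                p = 1.0
                for i in range(b + 1):
                    p *= 1.0 - (hz.get(y - i, race, b - i) if race is not None else 0.0)
                    for vc in value_cols:
                        val = tables[vc].get((y - i, *grp, b - i), 0.0)
                        totals[vc] += val * p
                rec = {"year": y, "child_age": b, "G_lifetime": totals["G_dedup"]}
                if "G_dedup_primary" in totals:
                    rec["G_lifetime_primary"] = totals["G_dedup_primary"]
                if "G_dedup_secondary" in totals:
                    rec["G_lifetime_secondary"] = totals["G_dedup_secondary"]
                rec.update(dict(zip(group_cols, grp)))
                records.append(rec)
    G_life = pd.DataFrame.from_records(records)

    keys = [c for c in ("year", "sex", "race_ethnicity", "state", "child_age", "cause") if c in O_lifetime.columns and c in G_life.columns]
    merged = O_lifetime.rename(columns={"lifetime": "O_lifetime"}).merge(G_life, on=keys, how="outer")
    fill_cols = [c for c in merged.columns if c.startswith(("O_lifetime", "G_lifetime"))]
    merged[fill_cols] = merged[fill_cols].fillna(0.0)
    merged["L_lifetime"] = merged["O_lifetime"] + merged["G_lifetime"]
    return merged
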