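"""Core orphanhood estimator.

The estimator attributes to each decedent the expected number of living
children of each age 0-17, built from lagged fertility rates and pediatric
survival, and combines these with stratified death counts:

* ``expected_children`` — C_{y,a,s,r,b} = FR_{y-b, band(a-b), s, r} x
  p_survive_{y-b, b+1}, averaged over single parental ages within 5-year
  bands (mothers 15-66, fathers 15-94 at death).
* ``mortality_hazard`` — band hazards nh_x = D / (n P), the mid-band
  life-table approximation (1/n) * 2q / (2 - q) with q = D / (P + D/2).
* ``incidence_components`` — per-stratum expected children newly bereaved by
  a parent's death, together with corrections for the other parent dying in
  the same year (assuming independent parental deaths) or in a previous
  year (lagged-hazard accumulation).
* ``combine_incidence`` — de-duplicated combined incidence and by-sex
  incidence (maternal and paternal counts each include double orphans).
* ``accumulate_prevalence`` — lifetime (prevalent) counts by accruing
  incidence over the current and previous 17 years while discounting for
  child mortality and excluding cohorts that aged past 17.

The other parent is assumed to be of the same age band and race/ethnicity as
the decedent, and all-cause hazards are used for the other parent's death
regardless of the decedent's cause category.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import bands
from .errors import AlignmentError, EstimationError
from .fertility import FertilityLookup

logger = logging.getLogger(__name__)

MAX_CHILD_AGE = 17


def hazard_from_q(D: np.ndarray | float, P: np.ndarray | float, n: np.ndarray | float):
    """Band hazard via the life-table form (1/n) * 2q / (2-q), q = D/(P + D/2).

    Algebraically identical to D / (n P); exposed for the identity check.
    """
    q = np.asarray(D, dtype=float) / (np.asarray(P, dtype=float) + np.asarray(D, dtype=float) / 2.0)
    return (1.0 / np.asarray(n, dtype=float)) * 2.0 * q / (2.0 - q)


def _max_age_at_birth(sex: str) -> int:
    return bands.MOTHER_MAX_AGE_AT_BIRTH if sex == "female" else bands.FATHER_MAX_AGE_AT_BIRTH


def _max_age_at_death(sex: str) -> int:
    return bands.MOTHER_MAX_AGE_AT_DEATH if sex == "female" else bands.FATHER_MAX_AGE_AT_DEATH


def _natal_bands(sex: str) -> list[str]:
    return bands.MOTHER_BANDS if sex == "female" else bands.FATHER_BANDS


def expected_children(
    fertility: FertilityLookup | pd.DataFrame,
    survival: pd.DataFrame,
    years: list[int],
    races: list[str] | None = None,
) -> pd.DataFrame:
    """Expected number of children aged b per decedent, by parental band.

    For each single parental age a (15 to the sex-specific maximum age at
    death) the expected count is the fertility rate of the natal age band
    containing a-b in year y-b times the probability that a child born in
    y-b survived to age b+1; ages with a-b outside the reproductive range
    contribute 0.  Band-level values are the mean over single ages within
    the band (the open 85+ band enumerates ages 85 to the maximum age at
    death).  Pediatric survival is not race-indexed.
    """
    if isinstance(fertility, pd.DataFrame):
        fertility = FertilityLookup(fertility)
    if races is None:
        races = sorted(fertility.rates["race_ethnicity"].unique())
    surv = survival.set_index(["birth_year", "age"])["p_survive"].to_dict()

    def p_survive(birth_year: int, b: int) -> float:
        try:
            return surv[(birth_year, b)]
        except KeyError:
            raise EstimationError(f"missing child survival for cohort {birth_year}, age {b}") from None

    records: list[dict] = []
    for sex in bands.SEXES:
        max_birth = _max_age_at_birth(sex)
        max_death = _max_age_at_death(sex)
        natal = _natal_bands(sex)
        for race in races:
            for band in bands.ADULT_BANDS:
                lo, hi = bands.parse_band(band)
                ages = list(range(lo, (hi if hi is not None else max_death) + 1))
                if not ages:
                    continue
                for y in years:
                    for b in range(MAX_CHILD_AGE + 1):
                        vals = []
                        for a in ages:
                            ab = a - b
                            if ab < bands.MIN_PARENT_AGE or ab > max_birth:
                                vals.append(0.0)
                                continue
                            nb = bands.band_for_age(ab, natal)
                            fr = fertility.rate(y - b, sex, race, nb)
                            vals.append(fr * p_survive(y - b, b))
                        records.append(
                            {
                                "year": y,
                                "age_band": band,
                                "sex": sex,
                                "race_ethnicity": race,
                                "child_age": b,
                                "expected_children": float(np.mean(vals)),
                            }
                        )
    return pd.DataFrame.from_records(records)


def mortality_hazard(
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    n: int | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Annualized band mortality hazard nh_x = D / (n P).

    Death counts are summed over causes (the hazard is all-cause).  ``n``
    defaults to the band width (5 for adult bands, 1 for single-age child
    strata).  Hazards exceeding 1 are clipped with a warning; a zero
    population denominator is an estimation error when ``strict``,
    otherwise such strata are dropped with a warning (small-area strata can
    empty out within a year).
    """
    keys = [c for c in ("year", "age_band", "sex", "race_ethnicity", "state") if c in deaths.columns]
    totals = deaths.groupby(keys, as_index=False, observed=True)["count"].sum()
    pop_keys = [c for c in keys if c in population.columns]
    if pop_keys != keys:
        raise AlignmentError("population table lacks required strata columns")
    merged = totals.merge(
        population[keys + ["count"]].rename(columns={"count": "pop"}), on=keys, how="left"
    )
    bad = merged["pop"].isna() | (merged["pop"] == 0)
    if bad.any():
        if strict:
            raise EstimationError("missing or zero population for a mortality stratum")
        logger.warning("dropping %d mortality strata with zero/missing population", int(bad.sum()))
        merged = merged[~bad]
    widths = merged["age_band"].map(bands.band_width) if n is None else n
    merged["n"] = widths
    hazard = merged["count"] / (merged["n"] * merged["pop"])
    if (hazard > 1).any():
        logger.warning("%d hazards exceed 1; clipped", int((hazard > 1).sum()))
    merged["hazard"] = hazard.clip(0.0, 1.0)
    merged["midpoint"] = merged["age_band"].map(bands.band_midpoint)
    return merged[keys + ["n", "midpoint", "hazard"]]


class _HazardIndex:
    """Fast (year, band) hazard lookup per (sex, race)."""

    def __init__(self, hazards: pd.DataFrame):
        self.years = np.array(sorted(hazards["year"].unique()))
        self.band_idx = {b: i for i, b in enumerate(bands.ADULT_BANDS)}
        self.mats: dict[tuple[str, str], np.ndarray] = {}
        for (sex, race), grp in hazards.groupby(["sex", "race_ethnicity"], observed=True):
            mat = np.zeros((len(self.years), len(bands.ADULT_BANDS)))
            yr_pos = {y: i for i, y in enumerate(self.years)}
            for _, row in grp.iterrows():
                if row["age_band"] in self.band_idx:
                    mat[yr_pos[row["year"]], self.band_idx[row["age_band"]]] = row["hazard"]
            self.mats[(sex, race)] = mat
        self._yr_pos = {int(y): i for i, y in enumerate(self.years)}

    def get(self, year: int, band: str, sex: str, race: str) -> float:
        key = (sex, race)
        if key not in self.mats:
            raise EstimationError(f"no hazards for sex={sex}, race={race}")
        if year not in self._yr_pos:
            raise EstimationError(f"missing hazard year {year} for sex={sex}, race={race}")
        return float(self.mats[key][self._yr_pos[year], self.band_idx[band]])

    def annual_prob(self, year: int, band: str, sex: str, race: str) -> float:
        """Annual probability that a band member dies in the year.

        The band hazard nh_x = D/(nP) is a density per year of age; the
        probability of dying within the calendar year is n x nh_x = D/P
        (capped at 1).  This is the quantity the double-loss corrections
        require for the other parent.
        """
        return min(bands.band_width(band) * self.get(year, band, sex, race), 1.0)


def _prior_loss_factors(
    hz: _HazardIndex, year: int, band: str, sex_opp: str, race: str
) -> np.ndarray:
    """Cumulative probability that the other parent died in any of the
    previous 1..b-1 years, for every child age b = 0..17.

    For each lag i the annual death probabilities of the other parent at
    the lagged band band(a - i) are averaged over the five single ages a in
    the decedent's band (lagged ages below 15 carry zero hazard); lag terms
    are summed over i = 1..b-1 and the cumulative probability is capped at
    1.
    """
    ages = bands.band_single_ages(band)[:5]
    mean_lag = np.zeros(MAX_CHILD_AGE)
    for i in range(1, MAX_CHILD_AGE):
        vals = []
        for a in ages:
            lag_band = bands.band_for_age(a - i)
            vals.append(hz.annual_prob(year - i, lag_band, sex_opp, race) if lag_band else 0.0)
        mean_lag[i] = float(np.mean(vals))
    factors = np.zeros(MAX_CHILD_AGE + 1)
    factors[1:] = np.minimum(np.cumsum(mean_lag), 1.0)
    # factors[b] = sum_{i=1..b-1} mean_lag[i]; note factors[0] = factors[1] = 0.
    return factors


def incidence_components(
    C: pd.DataFrame,
    deaths: pd.DataFrame,
    hazards: pd.DataFrame,
) -> pd.DataFrame:
    """Per-stratum incidence components before combining parental sexes.

    Returns rows (year, age_band, sex, race, child_age, cause) with:
    ``death_of_parent`` = C x D; ``new_double`` = annual probability that
    the opposite-sex parent (same band and race) died the same year x
    death_of_parent; ``previous`` = cumulative prior-year opposite-sex loss
    probability x death_of_parent.  The other-parent probabilities are the
    annual band death probabilities n x nh_x = D/P — the estimand the
    corrections are defined on — rather than the per-age-year density nh_x
    itself.
    """
    keys = ["year", "age_band", "sex", "race_ethnicity"]
    merged = deaths.rename(columns={"count": "deaths"}).merge(C, on=keys, how="inner")
    if merged.empty:
        raise AlignmentError("no overlapping strata between deaths and expected-children table")
    merged["death_of_parent"] = merged["expected_children"] * merged["deaths"]

    hz = _HazardIndex(hazards)
    opp = {"female": "male", "male": "female"}

    same_year = {}
    for y, band, s, r in merged[keys].drop_duplicates().itertuples(index=False):
        same_year[(y, band, s, r)] = hz.annual_prob(y, band, opp[s], r)
    merged["_h_same"] = [
        same_year[(y, band, s, r)] for y, band, s, r in merged[keys].itertuples(index=False)
    ]
    merged["new_double"] = merged["_h_same"] * merged["death_of_parent"]

    prior = {}
    for y, band, s, r in merged[keys].drop_duplicates().itertuples(index=False):
        prior[(y, band, s, r)] = _prior_loss_factors(hz, y, band, opp[s], r)
    merged["previous"] = [
        prior[(y, band, s, r)][b] * d
        for y, band, s, r, b, d in merged[
            keys + ["child_age", "death_of_parent"]
        ].itertuples(index=False)
    ]
    cols = keys + ["child_age", "cause", "death_of_parent", "new_double", "previous"]
    return merged[cols]


def combine_incidence(components: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combined and by-sex incidence from the per-sex components.

    Combined: new = dop_F + dop_M - (nd_F + nd_M)/2 - prev_F - prev_M per
    (year, band, race, child age, cause), floored at 0 with a warning (the
    double-loss terms for the two sexes are not identical when built from
    aggregate statistics, hence their average is subtracted).  By sex:
    new_s = sum over bands of (dop_s - prev_s); maternal and paternal
    incidence each include children losing both parents.
    """
    keys = ["year", "age_band", "race_ethnicity", "child_age", "cause"]
    pivot = components.pivot_table(
        index=keys,
        columns="sex",
        values=["death_of_parent", "new_double", "previous"],
        aggfunc="sum",
        fill_value=0.0,
    )
    missing = {"female", "male"} - set(components["sex"].unique())
    if missing:
        raise AlignmentError(f"components missing sex strata {sorted(missing)}")
    dop = pivot["death_of_parent"]
    nd = pivot["new_double"]
    prev = pivot["previous"]
    new = (
        dop["female"] + dop["male"] - (nd["female"] + nd["male"]) / 2.0 - prev["female"] - prev["male"]
    )
    if (new < 0).any():
        logger.warning("%d corrected incidence values below 0; floored", int((new < 0).sum()))
        new = new.clip(lower=0.0)
    combined = new.rename("new").reset_index()

    by_sex = (
        components.assign(new=components["death_of_parent"] - components["previous"])
        .groupby(["year", "sex", "race_ethnicity", "child_age", "cause"], as_index=False, observed=True)["new"]
        .sum()
    )
    return combined, by_sex


class ChildHazardIndex:
    """(year, age, race) child hazard lookup; strict on missing years."""

    def __init__(self, child_hazards: pd.DataFrame):
        age_col = "age" if "age" in child_hazards.columns else "age_band"
        df = child_hazards.copy()
        df["age"] = df[age_col].astype(str).map(lambda s: bands.parse_band(s)[0])
        self.years = sorted(df["year"].unique())
        self._yr_pos = {int(y): i for i, y in enumerate(self.years)}
        self.mats: dict[str, np.ndarray] = {}
        for race, grp in df.groupby("race_ethnicity", observed=True):
            mat = np.zeros((len(self.years), MAX_CHILD_AGE + 1))
            for _, row in grp.iterrows():
                mat[self._yr_pos[int(row["year"])], int(row["age"])] = row["hazard"]
            self.mats[race] = mat

    def get(self, year: int, race: str, age: int) -> float:
        if race not in self.mats:
            raise EstimationError(f"no child hazards for race {race}")
        if year not in self._yr_pos:
            raise EstimationError(f"missing child hazard year {year}")
        return float(self.mats[race][self._yr_pos[year], age])


def accumulate_prevalence(
    new: pd.DataFrame,
    child_hazards: pd.DataFrame,
    years: list[int],
    value_col: str = "new",
    computed_years: list[int] | None = None,
) -> pd.DataFrame:
    """Lifetime (prevalent) kin loss by accruing incidence while aging.

    lifetime_{y,r,b,c} = sum_{i=0..b} new_{y-i, r, b-i, c} x
    prod_{j=1..i} (1 - 1h_{y-j, r, b-j}); the survival product starts at
    j = 1 because incidence already conditions on survival through the year
    of loss.  Cohorts that aged past 17 drop out via the b - i >= 0 limit.
    Works for combined or by-sex incidence (a ``sex`` column, if present,
    becomes part of the grouping).  Requires the full 17-year incidence and
    child-hazard history for each requested year.
    """
    hz = ChildHazardIndex(child_hazards)
    group_cols = [c for c in ("sex", "race_ethnicity", "cause") if c in new.columns]
    sum_keys = ["year"] + group_cols + ["child_age"]
    flat = new.groupby(sum_keys, as_index=False, observed=True)[value_col].sum()

    # Years the caller declares computed count as true zeros when absent
    # from the data (e.g. no deaths in a small stratum that year).
    inc_years = set(flat["year"].unique()) | set(computed_years or [])
    needed = {y - i for y in years for i in range(MAX_CHILD_AGE + 1)}
    missing = needed - inc_years
    if missing:
        raise EstimationError(f"incomplete incidence history; missing years {sorted(missing)}")

    out_records: list[dict] = []
    races = sorted(new["race_ethnicity"].unique())
    # Survival products shared across causes/sexes within a race.
    surv: dict[tuple[str, int, int, int], float] = {}
    for race in races:
        for y in years:
            for b in range(MAX_CHILD_AGE + 1):
                p = 1.0
                surv[(race, y, b, 0)] = 1.0
                for i in range(1, b + 1):
                    p *= 1.0 - hz.get(y - i, race, b - i)
                    surv[(race, y, b, i)] = p

    table = flat.set_index(sum_keys)[value_col].to_dict()

    def lookup(year: int, grp: tuple, b: int) -> float:
        return table.get((year, *grp, b), 0.0)

    groups = flat[group_cols].drop_duplicates().itertuples(index=False) if group_cols else [()]
    for grp in groups:
        grp = tuple(grp)
        race = grp[group_cols.index("race_ethnicity")]
        for y in years:
            for b in range(MAX_CHILD_AGE + 1):
                total = 0.0
                for i in range(b + 1):
                    val = lookup(y - i, grp, b - i)
                    if val:
                        total += val * surv[(race, y, b, i)]
                rec = {"year": y, "child_age": b, "lifetime": total}
                rec.update(dict(zip(group_cols, grp)))
                out_records.append(rec)
    return pd.DataFrame.from_records(out_records)
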