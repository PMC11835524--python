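"""Family-level microsimulation with exact kin-loss truth.

The simulator generates a cohort of families (one mother, one father, their
children, and optionally a co-residing grandparent) under annual
discrete-time dynamics: births follow an age-band fertility schedule,
adult deaths follow age-band/sex/race hazards with a configured
cause-of-death mix, and child deaths follow single-age hazards.  Within a
year, births precede deaths.  Because every individual of the same age
band, sex and race carries the same mortality hazard, the aggregated tables
the simulator emits are exactly the statistical inputs the estimation
pipeline assumes, and the enumerated line-list truth is a valid oracle for
it.

The emitted tables cover the parent and grandparent generation (adult
mortality, natality, population) and the child generation (single-age
mortality, population, cohort survival); children who age past 17 leave the
simulation frame.  Co-residence proportions are emitted in ACS-style form
(sex totals, race share, most-responsible and skip-generation proportions,
with binomial 90% margins of error).

``true_kin_loss`` computes exact incident and prevalent kin-loss counts by
enumeration: a child enters combined incidence once, in the year of the
first qualifying parental death; maternal and paternal incidence each count
children who lose both parents; prevalence counts children under 18 alive
at the end of the year who ever experienced the loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import bands
from .errors import ConfigurationError, IntegrityError

# --- Default study conditions ------------------------------------------------
# Female fertility (births per woman-year) by 5-year band, a broadly US-like
# schedule; male rates are emergent from the father age structure.
DEFAULT_FERTILITY = {
    "15-19": 0.025,
    "20-24": 0.090,
    "25-29": 0.110,
    "30-34": 0.095,
    "35-39": 0.045,
    "40-44": 0.010,
    "45-49": 0.001,
}

# Adult all-cause hazards per year by band; male rates are scaled up.
DEFAULT_ADULT_HAZARD = {
    "15-19": 0.0005,
    "20-24": 0.0010,
    "25-29": 0.0012,
    "30-34": 0.0015,
    "35-39": 0.0020,
    "40-44": 0.0030,
    "45-49": 0.0045,
    "50-54": 0.0065,
    "55-59": 0.0095,
    "60-64": 0.0140,
    "65-69": 0.0200,
    "70-74": 0.0310,
    "75-79": 0.0490,
    "80-84": 0.0800,
    "85+": 0.1500,
}
DEFAULT_MALE_HAZARD_FACTOR = 1.6

# Child all-cause hazards by single age 0-17.
DEFAULT_CHILD_HAZARD = [0.006] + [0.0004] * 4 + [0.0002] * 10 + [0.0005] * 3

DEFAULT_CAUSE_MIX = {
    "drug_overdose": 0.08,
    "heart_disease": 0.24,
    "cancer": 0.30,
    "unintentional_injuries_excluding_drug_overdose": 0.08,
    "other": 0.30,
}

DEFAULT_RACE_MIX = {
    "non-Hispanic white": 0.60,
    "non-Hispanic Black": 0.20,
    "Hispanic": 0.20,
}

GP_ROLES = ("skip_gen", "most_responsible_not_sg", "co_reside_not_mr")


@dataclass
class SimConfig:
    """Microsimulation configuration; defaults define the study conditions.

    Hazards and probabilities are annual and must lie in [0, 1]; the three
    grandparent role probabilities (conditional on a family having a
    grandparent) may sum to at most 1, the residual being a non-co-residing
    grandparent who is not a caregiver.
    """

    years: tuple[int, int] = (1975, 2020)
    n_families: int = 50_000
    seed: int = 2025
    race_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_MIX))
    fertility: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FERTILITY))
    adult_hazard: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ADULT_HAZARD))
    male_hazard_factor: float = DEFAULT_MALE_HAZARD_FACTOR
    child_hazard: list[float] = field(default_factory=lambda: list(DEFAULT_CHILD_HAZARD))
    cause_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CAUSE_MIX))
    # Father birth-year offset above the mother's, uniform over [0, max].
    # The default keeps the male fertility support inside the 5-year natal
    # bands (fathers at most 54 at a birth), so banded rates represent the
    # single-age schedule without edge effects.
    max_father_age_gap: int = 5
    # Grandparents: probability a family has one; role probabilities given one.
    p_has_grandparent: float = 0.55
    gp_role_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "skip_gen": 0.04,
            "most_responsible_not_sg": 0.10,
            "co_reside_not_mr": 0.16,
        }
    )
    gp_age_gap: tuple[int, int] = (22, 36)
    # States and their population weights (single state by default).
    state_weights: Mapping[str, float] = field(default_factory=lambda: {"S1": 1.0})
    # Fertility-mortality coupling (sensitivity scenario emulation).
    dampen_scenario: str = "none"
    dampen_onset: int = 0

    def validate(self) -> None:
        for name, vals in (("fertility", self.fertility), ("adult_hazard", self.adult_hazard)):
            for band, v in vals.items():
                bands.parse_band(band)
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError(f"{name}[{band}]={v} outside [0, 1]")
        if any(not 0.0 <= h <= 1.0 for h in self.child_hazard) or len(self.child_hazard) != 18:
            raise ConfigurationError("child_hazard must be 18 values in [0, 1]")
        if not 0.0 <= self.p_has_grandparent <= 1.0:
            raise ConfigurationError("p_has_grandparent outside [0, 1]")
        role_sum = sum(self.gp_role_probs.get(r, 0.0) for r in GP_ROLES)
        if role_sum > 1.0 + 1e-12:
            raise ConfigurationError("grandparent role probabilities sum above 1")
        if abs(sum(self.cause_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("cause_mix must sum to 1")
        if self.years[0] >= self.years[1]:
            raise ConfigurationError("years must be an increasing range")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        kwargs = dict(d)
        if "years" in kwargs:
            kwargs["years"] = tuple(kwargs["years"])
        if "gp_age_gap" in kwargs:
            kwargs["gp_age_gap"] = tuple(kwargs["gp_age_gap"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class FamilyLineList:
    """Individual records with parent/child and grandparent links.

    ``individuals``: id, role (mother/father/child/grandparent), sex, race,
    state, birth_year, death_year (NaN while alive in the window),
    death_cause.  ``links``: child_id, mother_id, father_id.
    ``grandparent_roles``: grandparent_id, child_id, role.
    """

    individuals: pd.DataFrame
    links: pd.DataFrame
    grandparent_roles: pd.DataFrame
    config: SimConfig


def _band_index_by_age(hazard: Mapping[str, float], max_age: int = 120) -> np.ndarray:
    """hazard value per single age, 0 where no band applies."""
    out = np.zeros(max_age + 1)
    for band, h in hazard.items():
        lo, hi = bands.parse_band(band)
        hi = max_age if hi is None else min(hi, max_age)
        out[lo : hi + 1] = h
    return out


def simulate_cohort(config: SimConfig) -> FamilyLineList:
    """Run the annual-step family microsimulation; reproducible given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.years
    n = config.n_families

    races = list(config.race_mix)
    race_p = np.array([config.race_mix[r] for r in races], dtype=float)
    race_p = race_p / race_p.sum()
    fam_race = rng.choice(len(races), size=n, p=race_p)
    state_names = list(config.state_weights)
    state_p = np.array([config.state_weights[s] for s in state_names], dtype=float)
    fam_state = rng.choice(len(state_names), size=n, p=state_p / state_p.sum())

    # Parents: mother birth years span all reproductive ages over the window.
    mother_by = rng.integers(y0 - bands.MOTHER_MAX_AGE_AT_BIRTH, y1 - bands.MIN_PARENT_AGE + 1, size=n)
    father_by = mother_by - rng.integers(0, config.max_father_age_gap + 1, size=n)

    # Grandparents (maternal side), present for a subset of families.
    has_gp = rng.random(n) < config.p_has_grandparent
    gp_by = mother_by - rng.integers(config.gp_age_gap[0], config.gp_age_gap[1] + 1, size=n)
    gp_sex = rng.integers(0, 2, size=n)  # 0 female, 1 male
    role_p = np.array([config.gp_role_probs.get(r, 0.0) for r in GP_ROLES])
    role_draw = rng.random(n)
    gp_role = np.full(n, -1)  # -1: no co-residing role
    cum = np.cumsum(role_p)
    for k in range(len(GP_ROLES) - 1, -1, -1):
        gp_role[role_draw < cum[k]] = k
    gp_role[~has_gp] = -2  # no grandparent at all

    # Stack adults: mothers [0, n), fathers [n, 2n), grandparents [2n, 2n+m).
    # Grandparents are full members of the demographic frame from age 15 —
    # present in population denominators and exposed to the same band
    # hazards as parents at every age.  A frame that admits them only at
    # older ages would hand their deaths the undiluted fertility of bands
    # they never belonged to and bias the attribution of expected children.
    gp_idx = np.nonzero(has_gp)[0]
    m = len(gp_idx)
    adult_by = np.concatenate([mother_by, father_by, gp_by[gp_idx]])
    adult_sex = np.concatenate([np.zeros(n, int), np.ones(n, int), gp_sex[gp_idx]])
    adult_race = np.concatenate([fam_race, fam_race, fam_race[gp_idx]])
    adult_entry_age = np.full(2 * n + m, bands.MIN_PARENT_AGE)
    n_adults = len(adult_by)

    hf = _band_index_by_age(config.adult_hazard)
    hm = np.clip(hf * config.male_hazard_factor, 0.0, 1.0)
    haz_by_sex = np.stack([hf, hm])

    # Phase 1: adult death years (independent of births by construction).
    adult_death = np.full(n_adults, np.iinfo(np.int32).max, dtype=np.int64)
    alive = np.ones(n_adults, bool)
    for y in range(y0, y1 + 1):
        age = y - adult_by
        at_risk = alive & (age >= adult_entry_age)
        if not at_risk.any():
            continue
        h = haz_by_sex[adult_sex[at_risk], np.clip(age[at_risk], 0, 120)]
        dies = rng.random(at_risk.sum()) < h
        idx = np.nonzero(at_risk)[0][dies]
        adult_death[idx] = y
        alive[idx] = False

    causes = list(config.cause_mix)
    cause_p = np.array([config.cause_mix[c] for c in causes])
    adult_cause = np.full(n_adults, -1)
    dead = adult_death <= y1
    adult_cause[dead] = rng.choice(len(causes), size=int(dead.sum()), p=cause_p / cause_p.sum())

    # Phase 2: births.  Birth-first ordering: a parent dying in year y can
    # still have a child that year; both parents must not have died earlier.
    fr_by_age = _band_index_by_age({b: config.fertility[b] for b in config.fertility}, 60)
    mother_death = adult_death[:n]
    father_death = adult_death[n : 2 * n]
    child_by_list: list[np.ndarray] = []
    child_fam_list: list[np.ndarray] = []
    dampen = config.dampen_scenario != "none"
    if dampen:
        from .fertility import dampen_fertility

    for y in range(y0, y1 + 1):
        mage = y - mother_by
        eligible = (
            (mage >= bands.MIN_PARENT_AGE)
            & (mage <= bands.MOTHER_MAX_AGE_AT_BIRTH)
            & (mother_death >= y)
            & (father_death >= y)
        )
        if not eligible.any():
            continue
        rate = fr_by_age[np.clip(mage, 0, 60)]
        rate = np.where(eligible, rate, 0.0)
        if dampen:
            ttd_m = np.clip(mother_death - y, 0, 10_000).astype(float)
            ttd_f = np.clip(father_death - y, 0, 10_000).astype(float)
            fac_m = dampen_fertility(np.ones(n), ttd_m, config.dampen_scenario, config.dampen_onset)
            fac_f = dampen_fertility(np.ones(n), ttd_f, config.dampen_scenario, config.dampen_onset)
            rate = rate * fac_m * fac_f
        born = rng.random(n) < rate
        if born.any():
            fams = np.nonzero(born)[0]
            child_by_list.append(np.full(len(fams), y))
            child_fam_list.append(fams)

    child_by = np.concatenate(child_by_list) if child_by_list else np.empty(0, int)
    child_fam = np.concatenate(child_fam_list) if child_fam_list else np.empty(0, int)
    n_children = len(child_by)
    child_sex = rng.integers(0, 2, size=n_children)

    # Phase 3: child deaths by single-age hazards through age 17.
    ch = np.asarray(config.child_hazard)
    child_death = np.full(n_children, np.iinfo(np.int32).max, dtype=np.int64)
    calive = np.ones(n_children, bool)
    for a in range(18):
        yr = child_by + a
        at_risk = calive & (yr <= y1)
        if not at_risk.any():
            continue
        dies = rng.random(int(at_risk.sum())) < ch[a]
        idx = np.nonzero(at_risk)[0][dies]
        child_death[idx] = yr[idx]
        calive[idx] = False

    # Assemble line list.
    sex_lbl = np.array(["female", "male"])
    race_lbl = np.array(races)
    state_lbl = np.array(state_names)
    cause_lbl = np.array(causes)

    def death_col(death: np.ndarray) -> np.ndarray:
        return np.where(death <= y1, death, np.nan)

    adults = pd.DataFrame(
        {
            "id": np.arange(n_adults),
            "role": ["mother"] * n + ["father"] * n + ["grandparent"] * m,
            "sex": sex_lbl[adult_sex],
            "race": race_lbl[adult_race],
            "state": state_lbl[np.concatenate([fam_state, fam_state, fam_state[gp_idx]])],
            "birth_year": adult_by,
            "death_year": death_col(adult_death),
            "death_cause": np.where(dead, cause_lbl[np.clip(adult_cause, 0, None)], None),
            "family": np.concatenate([np.arange(n), np.arange(n), gp_idx]),
            "frame_entry_age": adult_entry_age,
        }
    )
    children = pd.DataFrame(
        {
            "id": np.arange(n_adults, n_adults + n_children),
            "role": "child",
            "sex": sex_lbl[child_sex],
            "race": race_lbl[fam_race[child_fam]],
            "state": state_lbl[fam_state[child_fam]],
            "birth_year": child_by,
            "death_year": death_col(child_death),
            "death_cause": None,
            "family": child_fam,
            "frame_entry_age": 0,
        }
    )
    individuals = pd.concat([adults, children], ignore_index=True)

    links = pd.DataFrame(
        {
            "child_id": children["id"].to_numpy(),
            "mother_id": child_fam,
            "father_id": child_fam + n,
        }
    )

    # Grandparent roles: the family's co-residing grandparent cares for all
    # of the family's children.
    gp_ids = {fam: 2 * n + i for i, fam in enumerate(gp_idx)}
    role_records = []
    for fam, cid in zip(child_fam, children["id"].to_numpy()):
        r = gp_role[fam]
        if r >= 0:
            role_records.append((gp_ids[fam], cid, GP_ROLES[r]))
    grandparent_roles = pd.DataFrame(
        role_records, columns=["grandparent_id", "child_id", "role"]
    )
    return FamilyLineList(individuals, links, grandparent_roles, config)


_FAR = float(np.iinfo(np.int32).max)


@dataclass
class TruthTable:
    """Exact kin-loss counts enumerated from the line list.

    ``incidence_by_sex``: children newly losing a mother (maternal) or
    father (paternal) per (year, child age, race, state, cause); children
    losing both parents appear under both sexes.  ``incidence_combined``:
    children at their first qualifying parental loss (counted once; a
    same-year double loss is attributed to the mother's cause).
    ``prevalence_*``: children under 18 alive at the end of the year who
    ever experienced the loss.  ``gp_incidence``: grandchildren losing a
    co-residing caregiver by role.  ``caregiver_*``: combined parent or
    grandparent-caregiver loss, de-duplicated per child.
    """

    incidence_by_sex: pd.DataFrame
    incidence_combined: pd.DataFrame
    prevalence_combined: pd.DataFrame
    prevalence_by_sex: pd.DataFrame
    gp_incidence: pd.DataFrame
    caregiver_incidence: pd.DataFrame
    caregiver_prevalence: pd.DataFrame


def _count(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    return df.groupby(keys, as_index=False, observed=True).size().rename(columns={"size": "count"})


def true_kin_loss(linelist: FamilyLineList, years: list[int] | None = None) -> TruthTable:
    """Brute-force enumeration of kin-loss incidence and prevalence."""
    ind = linelist.individuals
    links = linelist.links
    ids = set(ind["id"])
    for col in ("child_id", "mother_id", "father_id"):
        if not set(links[col]).issubset(ids):
            raise IntegrityError(f"dangling {col} in links")
    if not linelist.grandparent_roles.empty:
        if not set(linelist.grandparent_roles["grandparent_id"]).issubset(ids):
            raise IntegrityError("dangling grandparent_id")

    y0, y1 = linelist.config.years
    if years is None:
        years = list(range(y0, y1 + 1))

    per = ind.set_index("id")
    ch = links.merge(
        ind[ind["role"] == "child"][["id", "birth_year", "death_year", "race", "state"]],
        left_on="child_id",
        right_on="id",
    )
    ch["cdeath"] = ch["death_year"].fillna(_FAR)
    for parent, col in (("m", "mother_id"), ("f", "father_id")):
        ch[f"{parent}death"] = per.loc[ch[col], "death_year"].fillna(_FAR).to_numpy()
        ch[f"{parent}cause"] = per.loc[ch[col], "death_cause"].to_numpy()

    birth = ch["birth_year"].to_numpy()
    cdeath = ch["cdeath"].to_numpy()

    def qualifies(pdeath: np.ndarray) -> np.ndarray:
        age = pdeath - birth
        return (
            (pdeath >= y0)
            & (pdeath <= y1)
            & (age >= 0)
            & (age <= 17)
            & (cdeath >= pdeath)  # a child dying the same year still counts
        )

    qm = qualifies(ch["mdeath"].to_numpy())
    qf = qualifies(ch["fdeath"].to_numpy())

    by_sex_blocks = []
    for q, pd_col, cz_col, sex in ((qm, "mdeath", "mcause", "female"), (qf, "fdeath", "fcause", "male")):
        ev = ch[q].copy()
        ev["year"] = ev[pd_col].astype(int)
        ev["child_age"] = (ev["year"] - ev["birth_year"]).astype(int)
        ev["cause"] = ev[cz_col]
        ev["parent_sex"] = sex
        by_sex_blocks.append(ev[["year", "parent_sex", "child_age", "race", "state", "cause"]])
    by_sex_events = pd.concat(by_sex_blocks, ignore_index=True)
    incidence_by_sex = _count(by_sex_events, ["year", "parent_sex", "child_age", "race", "state", "cause"])

    mloss = np.where(qm, ch["mdeath"].to_numpy(), _FAR)
    floss = np.where(qf, ch["fdeath"].to_numpy(), _FAR)
    first_loss = np.minimum(mloss, floss)
    has_loss = first_loss < _FAR
    first_cause = np.where(mloss <= floss, ch["mcause"].to_numpy(), ch["fcause"].to_numpy())
    comb = ch[has_loss].copy()
    comb["year"] = first_loss[has_loss].astype(int)
    comb["child_age"] = (comb["year"] - comb["birth_year"]).astype(int)
    comb["cause"] = first_cause[has_loss]
    incidence_combined = _count(comb, ["year", "child_age", "race", "state", "cause"])

    # Grandparent caregiver loss (per linked grandchild).
    roles = linelist.grandparent_roles
    if roles.empty:
        gp_events = pd.DataFrame(columns=["year", "role", "child_age", "race", "state"])
        gloss_per_child = pd.Series(dtype=float)
    else:
        gr = roles.merge(
            ind[["id", "death_year"]].rename(columns={"id": "grandparent_id", "death_year": "gdeath"}),
            on="grandparent_id",
        ).merge(
            ind[ind["role"] == "child"][["id", "birth_year", "death_year", "race", "state"]].rename(
                columns={"id": "child_id"}
            ),
            on="child_id",
        )
        gr["gdeath"] = gr["gdeath"].fillna(_FAR)
        gr["cdeath"] = gr["death_year"].fillna(_FAR)
        gb = gr["birth_year"].to_numpy()
        gd = gr["gdeath"].to_numpy()
        gq = (gd >= y0) & (gd <= y1) & (gd - gb >= 0) & (gd - gb <= 17) & (gr["cdeath"].to_numpy() >= gd)
        gev = gr[gq].copy()
        gev["year"] = gev["gdeath"].astype(int)
        gev["child_age"] = (gev["year"] - gev["birth_year"]).astype(int)
        gp_events = gev[["year", "role", "child_age", "race", "state"]]
        gloss_per_child = gev.groupby("child_id")["gdeath"].min()
    gp_incidence = _count(gp_events, ["year", "role", "child_age", "race", "state"])

    # Combined caregiver loss: first loss across parents and caregiver
    # grandparents, one count per child.
    gp_first = np.full(len(ch), _FAR)
    if len(gloss_per_child):
        mapped = ch["child_id"].map(gloss_per_child)
        gp_first = mapped.fillna(_FAR).to_numpy()
    care_first = np.minimum(first_loss, gp_first)
    has_care = care_first < _FAR
    care = ch[has_care].copy()
    care["year"] = care_first[has_care].astype(int)
    care["child_age"] = (care["year"] - care["birth_year"]).astype(int)
    caregiver_incidence = _count(care, ["year", "child_age", "race", "state"])

    # Prevalence: alive at the end of year y, under 18, ever bereaved.
    prev_blocks, prev_sex_blocks, care_prev_blocks = [], [], []
    age_all = np.subtract.outer(np.asarray(years), birth)  # [year, child]
    for k, y in enumerate(years):
        age = age_all[k]
        alive = (age >= 0) & (age <= 17) & (cdeath > y)
        base = alive & (first_loss <= y)
        if base.any():
            blk = ch[base].copy()
            blk["year"] = y
            blk["child_age"] = age[base]
            prev_blocks.append(blk[["year", "child_age", "race", "state"]])
        for q, loss, sex in ((qm, mloss, "female"), (qf, floss, "male")):
            bs = alive & (loss <= y)
            if bs.any():
                blk = ch[bs].copy()
                blk["year"] = y
                blk["child_age"] = age[bs]
                blk["parent_sex"] = sex
                prev_sex_blocks.append(blk[["year", "parent_sex", "child_age", "race", "state"]])
        bc = alive & (care_first <= y)
        if bc.any():
            blk = ch[bc].copy()
            blk["year"] = y
            blk["child_age"] = age[bc]
            care_prev_blocks.append(blk[["year", "child_age", "race", "state"]])

    def _stack(blocks, keys):
        if not blocks:
            return pd.DataFrame(columns=keys + ["count"])
        return _count(pd.concat(blocks, ignore_index=True), keys)

    prevalence_combined = _stack(prev_blocks, ["year", "child_age", "race", "state"])
    prevalence_by_sex = _stack(prev_sex_blocks, ["year", "parent_sex", "child_age", "race", "state"])
    caregiver_prevalence = _stack(care_prev_blocks, ["year", "child_age", "race", "state"])

    return TruthTable(
        incidence_by_sex,
        incidence_combined,
        prevalence_combined,
        prevalence_by_sex,
        gp_incidence,
        caregiver_incidence,
        caregiver_prevalence,
    )


def emit_vital_tables(linelist: FamilyLineList, by_state: bool = False) -> dict[str, pd.DataFrame]:
    """Aggregate the line list into the pipeline's input tables.

    Returns mortality (adult 5-year bands plus child single ages), natality
    (mother and father bands), population (annual exposure counts, same
    band scheme), cohort child survival, and the ACS-style caregiver-proportion
    table.  Total emitted death counts equal the number of death events in
    the window; natality totals equal the number of birth events.
    """
    ind = linelist.individuals
    links = linelist.links
    cfg = linelist.config
    y0, y1 = cfg.years
    geo = ["state"] if by_state else []

    adults = ind[ind["role"] != "child"]
    children = ind[ind["role"] == "child"]

    band_of_age = np.array(
        [bands.band_for_age(a) or "" for a in range(151)], dtype=object
    )

    ad = adults[adults["death_year"].notna()].copy()
    ad["year"] = ad["death_year"].astype(int)
    ad["age"] = ad["year"] - ad["birth_year"]
    ad = ad[ad["age"] >= bands.MIN_PARENT_AGE]
    ad["age_band"] = band_of_age[np.clip(ad["age"].to_numpy(), 0, 150)]
    ad = ad.rename(columns={"race": "race_ethnicity", "death_cause": "cause"})
    mortality_adult = _count(ad, ["year", "age_band", "sex", "race_ethnicity"] + geo + ["cause"])

    cd = children[children["death_year"].notna()].copy()
    cd["year"] = cd["death_year"].astype(int)
    cd["age_band"] = (cd["year"] - cd["birth_year"]).astype(int).astype(str)
    cd["cause"] = "other"
    cd = cd.rename(columns={"race": "race_ethnicity"})
    mortality_child = _count(cd, ["year", "age_band", "sex", "race_ethnicity"] + geo + ["cause"])
    mortality = pd.concat([mortality_adult, mortality_child], ignore_index=True)
    mortality["suppressed"] = False

    # Natality by parental age band at birth.
    nat = links.merge(
        children[["id", "birth_year", "race", "state"]], left_on="child_id", right_on="id"
    )
    per = ind.set_index("id")
    nat["mage"] = nat["birth_year"] - per.loc[nat["mother_id"], "birth_year"].to_numpy()
    nat["fage"] = nat["birth_year"] - per.loc[nat["father_id"], "birth_year"].to_numpy()
    blocks = []
    for age_col, band_set, sex in (("mage", bands.MOTHER_BANDS, "female"), ("fage", bands.FATHER_BANDS, "male")):
        blk = nat.copy()
        blk["age_band"] = [bands.band_for_age(a, band_set) for a in blk[age_col]]
        blk["sex"] = sex
        blk = blk.rename(columns={"race": "race_ethnicity", "birth_year": "year"})
        blocks.append(_count(blk, ["year", "age_band", "sex", "race_ethnicity"] + geo))
    natality = pd.concat(blocks, ignore_index=True)

    # Annual exposure population counts, aggregated via integer-encoded keys.
    a_by = adults["birth_year"].to_numpy()
    a_death = adults["death_year"].fillna(_FAR).to_numpy()
    c_by = children["birth_year"].to_numpy()
    c_death = children["death_year"].fillna(_FAR).to_numpy()

    def _pop_counts(df: pd.DataFrame, by: np.ndarray, death: np.ndarray, band_labels: list[str], band_code, entry: np.ndarray | None = None) -> pd.DataFrame:
        sexes = ["female", "male"]
        races = sorted(df["race"].unique())
        states_ = sorted(df["state"].unique())
        sex_i = df["sex"].map({s: i for i, s in enumerate(sexes)}).to_numpy()
        race_i = df["race"].map({r: i for i, r in enumerate(races)}).to_numpy()
        state_i = df["state"].map({s: i for i, s in enumerate(states_)}).to_numpy()
        nb, ns, nr, nst = len(band_labels), 2, len(races), len(states_)
        recs = []
        for y in range(y0, y1 + 1):
            age = y - by
            code = band_code(age)
            # Exposure denominator: everyone alive during year y, including
            # those dying within it, so emitted rates are exact for the
            # annual Bernoulli process that generated the events.
            sel = (code >= 0) & (death >= y)
            if entry is not None:
                sel &= age >= entry
            if not sel.any():
                continue
            key = ((code[sel] * ns + sex_i[sel]) * nr + race_i[sel]) * nst + state_i[sel]
            cnt = np.bincount(key, minlength=nb * ns * nr * nst)
            nz = np.nonzero(cnt)[0]
            for k in nz:
                st = k % nst
                r = (k // nst) % nr
                s = (k // (nst * nr)) % ns
                b = k // (nst * nr * ns)
                recs.append((y, band_labels[b], sexes[s], races[r], states_[st], int(cnt[k])))
        out = pd.DataFrame(recs, columns=["year", "age_band", "sex", "race_ethnicity", "state", "count"])
        if not geo:
            out = out.groupby(["year", "age_band", "sex", "race_ethnicity"], as_index=False, observed=True)["count"].sum()
        return out

    adult_band_code = np.full(151, -1)
    for i, b in enumerate(bands.ADULT_BANDS):
        lo, hi = bands.parse_band(b)
        adult_band_code[lo : (150 if hi is None else hi) + 1] = i
    pop_adult = _pop_counts(
        adults, a_by, a_death, bands.ADULT_BANDS,
        lambda age: adult_band_code[np.clip(age, 0, 150)],
        entry=adults["frame_entry_age"].to_numpy(),
    )
    child_labels = [str(a) for a in range(18)]
    pop_child = _pop_counts(
        children, c_by, c_death, child_labels,
        lambda age: np.where((age >= 0) & (age <= 17), age, -1),
    )
    population = pd.concat([pop_adult, pop_child], ignore_index=True)

    # Cohort survival to age b+1 (race-aggregated).
    surv_records = []
    born_by_year = children.groupby("birth_year", observed=True).size()
    for yb, n_born in born_by_year.items():
        sel = c_by == yb
        for b in range(18):
            if yb + b > y1:
                break
            surv_records.append(
                {
                    "birth_year": int(yb),
                    "age": b,
                    "p_survive": float((c_death[sel] > yb + b).sum() / n_born),
                }
            )
    child_survival = pd.DataFrame.from_records(surv_records)

    caregiver = _emit_caregiver_proportions(linelist, by_state)
    return {
        "mortality": mortality,
        "natality": natality,
        "population": population,
        "child_survival": child_survival,
        "caregiver": caregiver,
    }


def _emit_caregiver_proportions(linelist: FamilyLineList, by_state: bool) -> pd.DataFrame:
    """ACS-style factorized co-residence proportions with binomial moe90.

    Caregiver status is a fixed attribute of role-holding grandparents; the
    sex-specific total, race share multiplier, most-responsible and
    skip-generation proportions are measured among adults 30+ alive at the
    end of each survey year (the last 11 years of the window).
    """
    ind = linelist.individuals
    roles = linelist.grandparent_roles
    y0, y1 = linelist.config.years
    survey_years = [y for y in range(y1 - 10, y1 + 1) if y >= y0]

    role_by_gp = (
        roles.groupby("grandparent_id")["role"].first() if not roles.empty else pd.Series(dtype=object)
    )
    adults = ind[ind["role"] != "child"].copy()
    adults["gp_role"] = adults["id"].map(role_by_gp)
    a_by = adults["birth_year"].to_numpy()
    a_death = adults["death_year"].fillna(_FAR).to_numpy()

    geo_vals = sorted(adults["state"].unique()) if by_state else [None]
    records = []
    for y in survey_years:
        age30 = (y - a_by >= 30) & (a_death > y)
        for geo in geo_vals:
            sel = age30 if geo is None else (age30 & (adults["state"].to_numpy() == geo))
            pool = adults[sel]
            n_all = len(pool)
            care = pool["gp_role"].notna()
            n_care = int(care.sum())
            gamma_all = n_care / n_all if n_all else 0.0
            mr = pool["gp_role"].isin(["skip_gen", "most_responsible_not_sg"])
            p_mr = float(mr.sum() / n_care) if n_care else 0.0
            sg = pool["gp_role"] == "skip_gen"
            q_sg = float(sg.sum() / mr.sum()) if mr.sum() else 0.0

            def moe(p, n):
                return 1.645 * float(np.sqrt(max(p * (1 - p), 1e-12) / max(n, 1)))

            for sex in ("female", "male"):
                psex = pool[pool["sex"] == sex]
                gs = float((psex["gp_role"].notna()).mean()) if len(psex) else 0.0
                for race in sorted(pool["race"].unique()):
                    pr_pool = pool[pool["race"] == race]
                    gr = float(pr_pool["gp_role"].notna().mean()) if len(pr_pool) else 0.0
                    p_race = gr / gamma_all if gamma_all > 0 else 0.0
                    rec = {
                        "year": y,
                        "sex": sex,
                        "race_ethnicity": race,
                        "gamma_coreside": gs,
                        "p_coreside_race": min(p_race, 1.0),
                        "p_most_responsible": p_mr,
                        "q_skip_gen": q_sg,
                        "moe90_gamma_coreside": moe(gs, len(psex)),
                        "moe90_p_coreside_race": moe(gr, len(pr_pool)),
                        "moe90_p_most_responsible": moe(p_mr, n_care),
                        "moe90_q_skip_gen": moe(q_sg, max(int(mr.sum()), 1)),
                    }
                    if geo is not None:
                        rec["state"] = geo
                    records.append(rec)
    return pd.DataFrame.from_records(records)


def upscale_state_tables(
    tables: dict[str, pd.DataFrame],
    factor: float,
    seed: int | np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Emulate a larger population from emitted per-state tables.

    Natality, population and child-mortality counts are scaled
    deterministically by ``factor``; adult mortality counts are redrawn as
    Poisson variables around smooth expected values ``factor x population x
    rate``, with rates pooled over years and states per (band, sex, cause).
    Unlike scaling the integer death counts directly, this yields cells
    whose expectations range continuously from far below to far above the
    public-table suppression threshold — the regime suppression imputation
    is designed for.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for name in ("natality", "population"):
        df = tables[name].copy()
        df["count"] = df["count"] * factor
        out[name] = df
    out["child_survival"] = tables["child_survival"]
    if "caregiver" in tables:
        out["caregiver"] = tables["caregiver"]

    mort = tables["mortality"]
    is_child = mort["age_band"].map(bands.is_child_band)
    child = mort[is_child].copy()
    child["count"] = child["count"] * factor
    adult = mort[~is_child]

    pop = tables["population"]
    adult_pop = pop[~pop["age_band"].map(bands.is_child_band)]
    # Smooth rates pooled over years and states (hazards are shared across
    # states in the generator, so pooling is consistent).
    keys = ["age_band", "sex", "cause"]
    d_pool = adult.groupby(keys, observed=True)["count"].sum()
    p_pool = adult_pop.groupby(["age_band", "sex"], observed=True)["count"].sum()
    rate = (d_pool / p_pool.reindex(d_pool.index.droplevel("cause")).to_numpy()).rename("rate").reset_index()

    cell_keys = [c for c in ("year", "age_band", "sex", "race_ethnicity", "state") if c in adult_pop.columns]
    cells = adult_pop[cell_keys + ["count"]].merge(rate, on=["age_band", "sex"], how="inner")
    lam = factor * cells["count"].to_numpy() * cells["rate"].to_numpy()
    cells["count"] = rng.poisson(lam)
    cells = cells[cells["count"] > 0].drop(columns=["rate"])
    adult_new = cells
    adult_new["suppressed"] = False
    child["suppressed"] = False
    out["mortality"] = pd.concat([adult_new, child], ignore_index=True)
    return out
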