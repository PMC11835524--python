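"""Reading, validation and harmonization of vital-statistics count tables.

The pipeline consumes normalized long-format CSV/TSV tables rather than raw
fixed-width registration files: mortality, natality and population counts
stratified by year, age band, sex, race and ethnicity (and cause for deaths),
pediatric cohort survival probabilities, cause-map and comparability-ratio
configuration tables, and ACS-style grandparent co-residence proportions.

Harmonization covers three steps that make four decades of registrations
comparable: mapping ICD-coded underlying causes of death to the 53 rankable
caregiver-loss categories (with drug-overdose sub-codes split out of suicide,
homicide and unintentional injury), standardizing race and Hispanic-origin
reporting to five categories, and multiplying ICD-9-era cause counts by
ICD-10 comparability ratios.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import bands
from .errors import ConfigurationError, DuplicateStratumError, SchemaError

logger = logging.getLogger(__name__)

#: Sentinel for records excluded from race/ethnicity standardization.
EXCLUDED = "EXCLUDED"

#: The five standardized race and ethnicity categories.
STANDARD_RACES = (
    "Hispanic",
    "non-Hispanic American Indian or Alaska Native",
    "non-Hispanic Asian or Pacific Islander",
    "non-Hispanic Black",
    "non-Hispanic white",
)

# Default raw-vocabulary mapping for non-Hispanic records.  Any Hispanic
# origin takes precedence regardless of race.
DEFAULT_RACE_MAP: dict[str, str] = {
    "white": "non-Hispanic white",
    "black": "non-Hispanic Black",
    "american indian or alaska native": "non-Hispanic American Indian or Alaska Native",
    "asian or pacific islander": "non-Hispanic Asian or Pacific Islander",
    "more than one race": EXCLUDED,
    "other": EXCLUDED,
    "unknown": EXCLUDED,
}

# ICD-10 and ICD-9 drug-overdose source codes.  These are re-categorized into
# the dedicated drug_overdose cause and must never map to the suicide,
# homicide or unintentional-injury categories.
ICD10_OVERDOSE_CODES = frozenset(
    [f"X{c}" for c in range(40, 45)]
    + [f"X{c}" for c in range(60, 65)]
    + ["X85"]
    + [f"Y{c}" for c in range(10, 15)]
)
ICD9_OVERDOSE_CODES = frozenset(
    [f"E{c}" for c in range(850, 859)]
    + [f"E950.{d}" for d in range(6)]
    + ["E962.0"]
    + [f"E980.{d}" for d in range(6)]
)
OVERDOSE_CAUSE = "drug_overdose"
_INJURY_CAUSES_EXCL_OD = frozenset(
    {
        "suicide_excluding_drug_overdose",
        "homicide_excluding_drug_overdose",
        "unintentional_injuries_excluding_drug_overdose",
    }
)
OTHER_CAUSE = "other"

_SCHEMAS: dict[str, list[str]] = {
    "mortality": ["year", "age_band", "sex", "race_ethnicity", "cause", "count"],
    "natality": ["year", "age_band", "sex", "race_ethnicity", "count"],
    "population": ["year", "age_band", "sex", "race_ethnicity", "count"],
    "child_survival": ["birth_year", "age", "p_survive"],
    "cause_map": ["source_code", "scheme", "target"],
    "comparability": ["cause", "ratio", "sd"],
    "caregiver": [
        "year",
        "sex",
        "race_ethnicity",
        "gamma_coreside",
        "p_coreside_race",
        "p_most_responsible",
        "q_skip_gen",
    ],
}
# Columns accepted beyond the required schema.
_OPTIONAL: dict[str, set[str]] = {
    "mortality": {"suppressed", "state"},
    "natality": {"suppressed", "state"},
    "population": {"state"},
    "child_survival": {"race_ethnicity"},
    "cause_map": set(),
    "comparability": set(),
    "caregiver": {
        "state",
        "moe90_gamma_coreside",
        "moe90_p_coreside_race",
        "moe90_p_most_responsible",
        "moe90_q_skip_gen",
    },
}
# Synonyms normalized on load.
_RENAMES = {"cause_code": "cause", "parent_age_band": "age_band", "parent_sex": "sex"}

SEXES = bands.SEXES


def _key_columns(df: pd.DataFrame, kind: str) -> list[str]:
    if kind == "child_survival":
        keys = ["birth_year", "age"]
        if "race_ethnicity" in df.columns:
            keys.append("race_ethnicity")
        return keys
    if kind == "cause_map":
        return ["source_code", "scheme"]
    if kind == "comparability":
        return ["cause"]
    keys = [c for c in _SCHEMAS[kind] if c not in ("count",)]
    if "state" in df.columns:
        keys.append("state")
    return keys


def validate_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Validate an in-memory table against the ``kind`` schema.

    Returns a normalized copy.  Raises :class:`SchemaError` on unknown or
    missing columns and negative counts, :class:`DuplicateStratumError` on
    repeated stratum keys (duplicates are never silently summed).
    """
    if kind not in _SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    df = df.rename(columns=_RENAMES).copy()
    required = _SCHEMAS[kind]
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{kind} table missing columns {sorted(missing)}")
    unknown = set(df.columns) - set(required) - _OPTIONAL[kind]
    if unknown:
        raise SchemaError(f"{kind} table has unknown columns {sorted(unknown)}")

    if "suppressed" in df.columns:
        df["suppressed"] = df["suppressed"].fillna(False).astype(bool)
    elif kind in ("mortality", "natality"):
        df["suppressed"] = False

    if "count" in df.columns:
        if "suppressed" in df.columns:
            bad = df["suppressed"] & df["count"].notna()
            if bad.any():
                raise SchemaError(
                    "suppressed flag and reported count are mutually exclusive"
                )
            unsup = ~df["suppressed"]
        else:
            unsup = pd.Series(True, index=df.index)
        if df.loc[unsup, "count"].isna().any():
            raise SchemaError(f"{kind} table has missing counts")
        if (df.loc[unsup, "count"] < 0).any():
            raise SchemaError(f"{kind} table has negative counts")

    if "age_band" in df.columns:
        df["age_band"] = df["age_band"].astype(str)
        for band in df["age_band"].unique():
            bands.parse_band(band)
    if "sex" in df.columns:
        bad_sex = set(df["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise SchemaError(f"unknown sex values {sorted(bad_sex)}")
    if kind == "child_survival":
        if ((df["p_survive"] < 0) | (df["p_survive"] > 1)).any():
            raise SchemaError("p_survive outside [0, 1]")
        if (~df["age"].between(0, 17)).any():
            raise SchemaError("child_survival age outside 0-17")
    if kind == "comparability":
        if (df["ratio"] <= 0).any():
            raise ConfigurationError("comparability ratios must be positive")
        if (df["sd"] < 0).any():
            raise ConfigurationError("comparability sds must be non-negative")
    if kind == "caregiver":
        for col in ("gamma_coreside", "p_coreside_race", "p_most_responsible", "q_skip_gen"):
            if ((df[col] < 0) | (df[col] > 1)).any():
                raise ConfigurationError(f"caregiver proportion {col} outside [0, 1]")

    keys = _key_columns(df, kind)
    dup = df.duplicated(subset=keys)
    if dup.any():
        first = df.loc[dup, keys].iloc[0].to_dict()
        raise DuplicateStratumError(f"duplicate stratum key in {kind} table: {first}")
    if kind == "cause_map":
        _check_overdose_mapping(df)
    return df.reset_index(drop=True)


def _check_overdose_mapping(cause_map: pd.DataFrame) -> None:
    od_codes = ICD10_OVERDOSE_CODES | ICD9_OVERDOSE_CODES
    bad = cause_map[
        cause_map["source_code"].isin(od_codes)
        & cause_map["target"].isin(_INJURY_CAUSES_EXCL_OD | {"suicide", "homicide", "unintentional_injuries"})
    ]
    if not bad.empty:
        raise ConfigurationError(
            "drug-overdose source codes may not map to suicide/homicide/"
            f"unintentional categories: {bad['source_code'].tolist()}"
        )


def load_vital_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a long-format CSV/TSV vital-statistics table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return validate_table(df, kind)


def map_causes(deaths: pd.DataFrame, cause_map: pd.DataFrame) -> pd.DataFrame:
    """Aggregate death counts from source ICD codes to rankable causes.

    Codes absent from the map fall to the ``other`` category.  Total deaths
    per (year, age band, sex, race) stratum are conserved exactly.
    """
    cause_map = validate_table(cause_map, "cause_map")
    multi = cause_map.groupby("source_code")["target"].nunique()
    conflicted = multi[multi > 1]
    if not conflicted.empty:
        raise ConfigurationError(
            f"source codes mapped to multiple targets: {list(conflicted.index)}"
        )
    lookup = dict(zip(cause_map["source_code"], cause_map["target"]))
    out = deaths.copy()
    out["cause"] = out["cause"].map(lambda c: lookup.get(c, OTHER_CAUSE))
    keys = [c for c in ("year", "age_band", "sex", "race_ethnicity", "state", "cause") if c in out.columns]
    out = out.groupby(keys, as_index=False, observed=True)["count"].sum()
    out["suppressed"] = False
    return out


def standardize_race(
    race_code: str,
    hispanic_origin: bool | str,
    mapping: dict[str, str] | None = None,
) -> str:
    """Map raw race and Hispanic-origin reporting to a standardized category.

    Any record of Hispanic origin maps to ``Hispanic`` regardless of race;
    records of more than one race map to the :data:`EXCLUDED` sentinel and
    are dropped from downstream totals.  Raw codes outside the configured
    vocabulary raise :class:`ConfigurationError`.
    """
    if isinstance(hispanic_origin, str):
        hispanic_origin = hispanic_origin.strip().lower() in ("yes", "true", "hispanic", "1")
    if hispanic_origin:
        return "Hispanic"
    mapping = DEFAULT_RACE_MAP if mapping is None else mapping
    key = str(race_code).strip().lower()
    if key not in mapping:
        raise ConfigurationError(f"unmapped raw race code {race_code!r}")
    return mapping[key]


def drop_excluded(df: pd.DataFrame) -> pd.DataFrame:
    """Remove EXCLUDED race records, logging how many were dropped."""
    mask = df["race_ethnicity"] == EXCLUDED
    if mask.any():
        n = int(df.loc[mask, "count"].sum()) if "count" in df.columns else int(mask.sum())
        logger.info("dropping %d records with excluded race/ethnicity", n)
    return df[~mask].reset_index(drop=True)


def apply_comparability(
    deaths: pd.DataFrame,
    ratios: pd.DataFrame,
    years: Iterable[int],
) -> pd.DataFrame:
    """Multiply ICD-9-era cause counts by ICD-10 comparability ratios.

    Only rows whose year lies in ``years`` (the ICD-9-coded range, pre-1999
    in the study design) are adjusted; causes missing from the ratio table
    use a ratio of 1.  Counts are real-valued downstream of this step; no
    re-rounding is applied.
    """
    ratios = validate_table(ratios, "comparability")
    lookup = dict(zip(ratios["cause"], ratios["ratio"]))
    years = set(int(y) for y in years)
    out = deaths.copy()
    in_scope = out["year"].isin(years)
    out["count"] = out["count"].astype(float)
    if in_scope.any():
        factors = out.loc[in_scope, "cause"].map(lambda c: lookup.get(c, 1.0))
        out.loc[in_scope, "count"] = out.loc[in_scope, "count"] * factors.to_numpy()
    return out


def redistribute_race_by_composition(
    deaths: pd.DataFrame,
    target_year: int,
    composition_year: int,
) -> pd.DataFrame:
    """Attribute one year's race-unstratified deaths using another year's
    race composition per (age band, sex, cause) stratum.

    Used for years in which race reporting is unavailable (1983 in the study
    design, attributed using 1984 compositions).  Rows of the target year are
    expanded to one row per race with counts split proportionally; strata
    with no composition information are left unchanged.
    """
    comp = deaths[deaths["year"] == composition_year]
    if comp.empty:
        raise ConfigurationError(f"no rows for composition year {composition_year}")
    keys = ["age_band", "sex", "cause"]
    shares = comp.groupby(keys + ["race_ethnicity"], as_index=False, observed=True)["count"].sum()
    totals = shares.groupby(keys, observed=True)["count"].transform("sum")
    shares["share"] = np.where(totals > 0, shares["count"] / totals, np.nan)
    shares = shares.drop(columns="count")

    target = deaths[deaths["year"] == target_year]
    rest = deaths[deaths["year"] != target_year]
    merged = target.drop(columns=["race_ethnicity"]).merge(shares, on=keys, how="left")
    merged = merged.dropna(subset=["share"])
    merged["count"] = merged["count"] * merged["share"]
    merged = merged.drop(columns="share")
    return pd.concat([rest, merged], ignore_index=True)
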