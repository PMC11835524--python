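"""State-level estimation: suppression handling and national rescaling.

Public state tabulations suppress small counts (below 10 in CDC-WONDER-style
tables), so state-level estimation proceeds in two stages: suppressed cells
are imputed with a small constant, then state mortality counts are rescaled
so their sum matches the national counts per (year, age band, sex, cause)
stratum (the eta factors).  After running the orphanhood estimator per
state, a second correction (the nu factors, per year/sex/cause only,
deliberately not age-specific) aligns summed state incidence with the
national estimate; residual discrepancies stay within 0.5%.

Fertility series with missing years (suppressed or unreported) are filled by
tricube-weighted local linear regression (LOESS, span 0.85); trailing gaps
carry the last observed value forward.  Race-stratified state estimates pass
reliability screens before being reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Counts strictly below this threshold are suppressed in public state tables.
SUPPRESSION_THRESHOLD = 10

_IMPUTE_VALUES = {"state": 2.0, "state_race": 1.0}


def suppress_small_counts(df: pd.DataFrame, threshold: int = SUPPRESSION_THRESHOLD) -> pd.DataFrame:
    """Mask counts below ``threshold`` as suppressed (synthetic suppressor
    mirroring public-table disclosure rules); used to build test inputs."""
    out = df.copy()
    mask = out["count"] < threshold
    out["suppressed"] = mask
    out["count"] = out["count"].where(~mask)
    return out


def impute_suppressed(counts: pd.DataFrame, mode: str = "state") -> pd.DataFrame:
    """Replace suppressed cells with a small constant: 2 in state mode, 1 in
    state-by-race mode.  The suppression flags are retained for audit."""
    if mode not in _IMPUTE_VALUES:
        raise ConfigurationError(f"unknown imputation mode {mode!r}")
    out = counts.copy()
    if "suppressed" not in out.columns:
        out["suppressed"] = False
    mask = out["suppressed"].eq(True)
    out["count"] = out["count"].astype(float)
    out.loc[mask, "count"] = _IMPUTE_VALUES[mode]
    return out


def rescale_to_national(
    state_counts: pd.DataFrame,
    national_counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescale state mortality counts to the national totals.

    eta_{y,a',s,c} = D_national / sum_l D_state; adjusted counts
    D* = eta x D_state.  Strata whose state sum is zero while the national
    count is positive (fully suppressed strata) are flagged and keep
    eta = 1 with a warning.  Returns (adjusted counts, audit table).
    """
    keys = ["year", "age_band", "sex", "cause"]
    keys = [k for k in keys if k in national_counts.columns]
    nat = national_counts.groupby(keys, as_index=False, observed=True)["count"].sum()
    nat = nat.rename(columns={"count": "national"})
    state_sum = state_counts.groupby(keys, as_index=False, observed=True)["count"].sum()
    state_sum = state_sum.rename(columns={"count": "state_sum"})
    audit = nat.merge(state_sum, on=keys, how="left")
    audit["state_sum"] = audit["state_sum"].fillna(0.0)
    zero = audit["state_sum"] == 0
    flagged = zero & (audit["national"] > 0)
    if flagged.any():
        logger.warning("%d strata fully suppressed across states; eta set to 1", int(flagged.sum()))
    audit["eta"] = np.where(zero, 1.0, audit["national"] / audit["state_sum"].where(~zero, 1.0))
    audit["flag"] = np.where(flagged, "fully_suppressed", "")

    adjusted = state_counts.merge(audit[keys + ["eta"]], on=keys, how="left")
    adjusted["eta"] = adjusted["eta"].fillna(1.0)
    adjusted["count"] = adjusted["count"] * adjusted["eta"]
    adjusted = adjusted.drop(columns=["eta"])
    return adjusted, audit


def smooth_fertility_series(
    series: pd.Series,
    span: float = 0.85,
) -> pd.Series:
    """Fill missing years of a fertility-rate series by LOESS interpolation.

    ``series`` is indexed by year with NaN for missing years.  The smoother
    is tricube-weighted local linear regression with the given span
    fraction; fitted values replace missing interior years, observed years
    are kept as observed, and trailing gaps carry the last observed value
    forward.  With fewer than 4 observed points the series falls back to
    carry-forward/backward filling with a warning.
    """
    if not 0 < span <= 1:
        raise ConfigurationError("span must be in (0, 1]")
    years = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    if observed.sum() < 4:
        logger.warning("fewer than 4 observed points; carry-forward fill")
        return series.ffill().bfill()
    fitted = lowess(
        vals[observed], years[observed], frac=span, it=0, xvals=years
    )
    out = np.where(observed, vals, fitted)
    # Trailing gaps beyond the last observation carry the last observed value.
    last_obs = np.max(np.nonzero(observed)[0])
    if last_obs < len(out) - 1:
        out[last_obs + 1 :] = vals[last_obs]
    first_obs = np.min(np.nonzero(observed)[0])
    if first_obs > 0:
        out[:first_obs] = vals[first_obs]
    return pd.Series(out, index=series.index, name=series.name)


def state_correction(
    state_incidence: pd.DataFrame,
    national_incidence: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correct state orphanhood incidence to the national totals.

    nu_{y,s,c} = national incidence (summed over race, band, child age) /
    summed state incidence, applied uniformly across ages and states:
    O^new* = nu x O^new.  Zero state sums are flagged with nu = 1.
    Returns (corrected incidence, audit table).
    """
    keys = [k for k in ("year", "sex", "cause") if k in state_incidence.columns and k in national_incidence.columns]
    nat = national_incidence.groupby(keys, as_index=False, observed=True)["new"].sum()
    nat = nat.rename(columns={"new": "national"})
    st = state_incidence.groupby(keys, as_index=False, observed=True)["new"].sum()
    st = st.rename(columns={"new": "state_sum"})
    audit = nat.merge(st, on=keys, how="left")
    audit["state_sum"] = audit["state_sum"].fillna(0.0)
    zero = audit["state_sum"] == 0
    flagged = zero & (audit["national"] > 0)
    if flagged.any():
        logger.warning("%d incidence strata with zero state sum; nu set to 1", int(flagged.sum()))
    audit["nu"] = np.where(zero, 1.0, audit["national"] / audit["state_sum"].where(~zero, 1.0))
    audit["flag"] = np.where(flagged, "zero_state_sum", "")

    corrected = state_incidence.merge(audit[keys + ["nu"]], on=keys, how="left")
    corrected["nu"] = corrected["nu"].fillna(1.0)
    corrected["new"] = corrected["new"] * corrected["nu"]
    corrected = corrected.drop(columns=["nu"])
    return corrected, audit


def reliability_screen(
    births: pd.DataFrame,
    deaths: pd.DataFrame,
    race_state_incidence: pd.DataFrame | None = None,
    state_incidence: pd.DataFrame | None = None,
    min_count: int = 20,
    max_small_bands: int = 2,
    max_shortfall: float = 0.20,
) -> pd.DataFrame:
    """Flag (state, race) strata whose estimates are unreliable.

    A stratum is flagged ``small_populations`` when more than two age bands
    have fewer than 20 live births, ``small_death_counts`` analogously for
    deaths, and ``large_discrepancy_in_estimates`` when the race-summed
    incidence falls more than 20% below the state estimate.  Returns one
    row per (state, race) with an ``include`` flag and the reasons.
    """
    def _small(df: pd.DataFrame) -> pd.Series:
        per_band = df.groupby(["state", "race_ethnicity", "age_band"], observed=True)["count"].sum()
        small = per_band < min_count
        return small.groupby(level=["state", "race_ethnicity"]).sum()

    small_births = _small(births)
    small_deaths = _small(deaths)
    idx = small_births.index.union(small_deaths.index)
    out = pd.DataFrame(index=idx)
    out["n_small_birth_bands"] = small_births.reindex(idx, fill_value=0)
    out["n_small_death_bands"] = small_deaths.reindex(idx, fill_value=0)
    reasons = []
    for _, row in out.iterrows():
        r = []
        if row["n_small_birth_bands"] > max_small_bands:
            r.append("small_populations")
        if row["n_small_death_bands"] > max_small_bands:
            r.append("small_death_counts")
        reasons.append(r)

    if race_state_incidence is not None and state_incidence is not None:
        race_sum = race_state_incidence.groupby("state", observed=True)["new"].sum()
        state_tot = state_incidence.groupby("state", observed=True)["new"].sum()
        shortfall = 1.0 - race_sum / state_tot.reindex(race_sum.index)
        for i, (state, _race) in enumerate(out.index):
            if state in shortfall.index and shortfall.loc[state] > max_shortfall:
                reasons[i].append("large_discrepancy_in_estimates")

    out = out.reset_index()
    out["reasons"] = [",".join(r) for r in reasons]
    out["include"] = out["reasons"] == ""
    return out
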