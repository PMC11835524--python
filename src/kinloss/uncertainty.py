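"""Monte Carlo uncertainty propagation for count-based estimates.

Uncertainty is phenomenological: Poisson noise is added around every
mortality, natality and population count, comparability ratios and survey
proportions are resampled from normal distributions, the full pipeline is
re-run per replicate, and pointwise 2.5%/50%/97.5% quantiles summarize the
ensemble.

Poisson replicates are co-monotonized across years within each stratum: the
n_rep draws for every year of a stratum are sorted and replicate k receives
the k-th order statistic in every year, making each replicate consistently
high or low over time.  This maximizes positive temporal dependence (and
hence uncertainty in trends) without changing any per-cell marginal
distribution.  Co-monotonization is applied across years only, not across
strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EstimationError

#: Two-sided 90% normal quantile used to convert ACS margins of error to sds.
MOE90_Z = 1.645

#: Conventional replicate count for full uncertainty runs.
DEFAULT_N_REP = 1000


def poisson_comonotone(
    counts: pd.DataFrame,
    n_rep: int,
    seed: int | np.random.Generator,
    value_col: str = "count",
) -> pd.DataFrame:
    """Co-monotone Poisson replicate ensemble of a stratified count table.

    Returns the input table with replicate columns ``rep_0 .. rep_{n-1}``:
    for each cell, n_rep Poisson(count) draws sorted ascending, so within
    any stratum replicate k is non-decreasing in k for every year
    simultaneously.
    """
    if n_rep < 2:
        raise ConfigurationError("n_rep must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = counts[value_col].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ConfigurationError("counts must be non-negative")
    draws = rng.poisson(lam=vals[:, None], size=(len(vals), n_rep))
    draws.sort(axis=1)
    out = counts.copy()
    rep_cols = pd.DataFrame(
        draws, columns=[f"rep_{k}" for k in range(n_rep)], index=counts.index
    )
    return pd.concat([out, rep_cols], axis=1)


def resample_ratios(
    medians: np.ndarray | pd.Series,
    sds: np.ndarray | pd.Series | None,
    n_rep: int,
    seed: int | np.random.Generator,
    moe90: np.ndarray | pd.Series | None = None,
) -> np.ndarray:
    """Normal resamples of ratios or proportions, truncated at 0.

    Either standard deviations or 90% margins of error may be supplied;
    margins of error are converted by dividing by 1.645.  Returns an array
    of shape (n_values, n_rep).
    """
    med = np.asarray(medians, dtype=float)
    if moe90 is not None:
        if sds is not None:
            raise ConfigurationError("supply sds or moe90, not both")
        sds = np.asarray(moe90, dtype=float) / MOE90_Z
    sds = np.zeros_like(med) if sds is None else np.asarray(sds, dtype=float)
    if np.any(sds < 0):
        raise ConfigurationError("standard deviations must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.normal(loc=med[:, None], scale=sds[:, None], size=(len(med), n_rep))
    return np.clip(draws, 0.0, None)


def moe90_to_sd(moe90: float | np.ndarray) -> float | np.ndarray:
    """Convert a 90% margin of error to a standard deviation (divide by 1.645)."""
    return np.asarray(moe90, dtype=float) / MOE90_Z


def summarize(replicates: np.ndarray | pd.DataFrame, axis: int = -1) -> pd.DataFrame:
    """Pointwise median and 95% uncertainty interval of an ensemble.

    Quantiles use linear interpolation between order statistics (declared
    in the output metadata via the ``quantile_method`` attribute).  Derived
    quantities (rates, percent changes) must be computed per replicate
    before summarizing.
    """
    arr = replicates.to_numpy() if isinstance(replicates, pd.DataFrame) else np.asarray(replicates)
    if arr.size == 0 or arr.shape[axis] < 2:
        raise EstimationError("need at least 2 replicates to summarize")
    med = np.median(arr, axis=axis)
    lo = np.quantile(arr, 0.025, axis=axis, method="linear")
    hi = np.quantile(arr, 0.975, axis=axis, method="linear")
    out = pd.DataFrame({"median": np.atleast_1d(med), "lo95": np.atleast_1d(lo), "hi95": np.atleast_1d(hi)})
    out.attrs["quantile_method"] = "linear"
    return out
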