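"""Derived summaries and the configuration-driven pipeline runner.

Summaries mirror the trend-table layout of the study: incidence and
prevalence counts by component (orphanhood, primary and secondary
grandparent-caregiver loss, and their de-duplicated total), rates per 100
children, and percent changes between named year pairs.  When an ensemble
of replicate estimates is supplied, every derived quantity — rates and
percent changes included — is computed per replicate before the median and
95% uncertainty interval are taken, so interval endpoints of a change
column are quantiles of per-replicate changes, not changes of quantiles.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pipeline, synthetic, uncertainty
from .errors import ConfigurationError, EstimationError
from .vitals_io import load_vital_table

logger = logging.getLogger(__name__)

COMPONENTS = ("total", "orphanhood", "primary_grandparent", "secondary_grandparent")


def percent_change(old: float, new: float, decimals: int | None = 1) -> float:
    """Percent change 100 x (new - old) / old, reported to one decimal.

    A non-positive baseline is undefined and raises an estimation error.
    """
    if old <= 0:
        raise EstimationError(f"percent change undefined for baseline {old}")
    pct = 100.0 * (new - old) / old
    return round(pct, decimals) if decimals is not None else pct


def component_totals(est: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Annual component totals from a pipeline-estimate dict.

    Incidence components come from the combined orphanhood incidence and
    the de-duplicated grandparent splits; prevalence components from the
    orphanhood lifetime table and accumulated grandparent contributions.
    Returns long rows (measure, component, year, count).
    """
    rows = []
    inc_o = est["new_combined"].groupby("year")["new"].sum()
    gd = est["G_dedup"].groupby("year")[["G_dedup_primary", "G_dedup_secondary"]].sum()
    for y in inc_o.index:
        o = float(inc_o.loc[y])
        p = float(gd["G_dedup_primary"].get(y, 0.0))
        s = float(gd["G_dedup_secondary"].get(y, 0.0))
        rows += [
            ("incidence", "orphanhood", int(y), o),
            ("incidence", "primary_grandparent", int(y), p),
            ("incidence", "secondary_grandparent", int(y), s),
            ("incidence", "total", int(y), o + p + s),
        ]
    prev_o = est["lifetime"].groupby("year")["lifetime"].sum()
    life = est["L_lifetime"]
    # The by-sex orphanhood lifetime double-counts double orphans, so the
    # combined lifetime table is the orphanhood prevalence component.
    gp = life.groupby("year")[["G_lifetime_primary", "G_lifetime_secondary"]].sum()
    for y in prev_o.index:
        o = float(prev_o.loc[y])
        p = float(gp["G_lifetime_primary"].get(y, 0.0))
        s = float(gp["G_lifetime_secondary"].get(y, 0.0))
        rows += [
            ("prevalence", "orphanhood", int(y), o),
            ("prevalence", "primary_grandparent", int(y), p),
            ("prevalence", "secondary_grandparent", int(y), s),
            ("prevalence", "total", int(y), o + p + s),
        ]
    return pd.DataFrame(rows, columns=["measure", "component", "year", "count"])


def child_population_by_year(population: pd.DataFrame) -> pd.Series:
    """Total children 0-17 per year from the single-age population strata."""
    _, child = pipeline.split_child_strata(population)
    return child.groupby("year")["count"].sum()


def build_summary(
    totals_runs: list[pd.DataFrame],
    child_population: pd.Series,
    change_pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Trend summary with rates per 100 children and percent changes.

    ``totals_runs`` holds one :func:`component_totals` frame per replicate
    (a single frame gives a point summary with degenerate intervals).
    Rates and changes are computed per replicate before summarizing; the
    point value of a change is the median of per-replicate changes, with
    the change of medians also reported for transparency.
    """
    if not totals_runs:
        raise EstimationError("no estimate runs supplied")
    change_pairs = change_pairs or []
    base = totals_runs[0][["measure", "component", "year"]]
    counts = np.stack([t["count"].to_numpy(dtype=float) for t in totals_runs], axis=1)
    missing_years = set(base["year"]) - set(child_population.index)
    if missing_years:
        raise EstimationError(f"child population missing for years {sorted(missing_years)}")
    pop = base["year"].map(child_population).to_numpy(dtype=float)
    rates = counts / pop[:, None] * 100.0

    def _summ(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if mat.shape[1] == 1:
            v = mat[:, 0]
            return v, v, v
        return (
            np.median(mat, axis=1),
            np.quantile(mat, 0.025, axis=1),
            np.quantile(mat, 0.975, axis=1),
        )

    out = base.copy()
    for name, mat in (("count", counts), ("rate_per_100", rates)):
        med, lo, hi = _summ(mat)
        out[name] = med
        out[f"{name}_lo95"] = lo
        out[f"{name}_hi95"] = hi

    for y_old, y_new in change_pairs:
        col = f"change_{y_old}_{y_new}_pct"
        vals = np.full((len(base), counts.shape[1]), np.nan)
        for measure, component in base[["measure", "component"]].drop_duplicates().itertuples(index=False):
            sel_old = (base["measure"] == measure) & (base["component"] == component) & (base["year"] == y_old)
            sel_new = (base["measure"] == measure) & (base["component"] == component) & (base["year"] == y_new)
            if not sel_old.any() or not sel_new.any():
                continue
            old = counts[sel_old.to_numpy()][0]
            new = counts[sel_new.to_numpy()][0]
            if np.any(old <= 0):
                continue
            change = 100.0 * (new - old) / old
            vals[sel_new.to_numpy()] = change
        med, lo, hi = _summ(vals)
        out[col] = np.round(med, 1)
        out[f"{col}_lo95"] = np.round(lo, 1)
        out[f"{col}_hi95"] = np.round(hi, 1)
        # Change of medians, for transparency alongside the median change.
        med_counts = np.median(counts, axis=1) if counts.shape[1] > 1 else counts[:, 0]
        com = np.full(len(base), np.nan)
        for measure, component in base[["measure", "component"]].drop_duplicates().itertuples(index=False):
            sel_old = (base["measure"] == measure) & (base["component"] == component) & (base["year"] == y_old)
            sel_new = (base["measure"] == measure) & (base["component"] == component) & (base["year"] == y_new)
            if sel_old.any() and sel_new.any() and med_counts[sel_old.to_numpy()][0] > 0:
                com[sel_new.to_numpy()] = percent_change(
                    med_counts[sel_old.to_numpy()][0], med_counts[sel_new.to_numpy()][0]
                )
        out[f"{col}_of_medians"] = com
    return out


# --- Configuration-driven runner ---------------------------------------------

_REQUIRED_TABLES = ("mortality", "natality", "population", "child_survival", "caregiver")


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the configured estimation end to end and write artifacts.

    The configuration names the input tables, estimation years, replicate
    count, seed and mode (national | state).  Outputs — incidence,
    prevalence, caregiver-loss and summary tables plus a run log recording
    every effective setting — are written as CSV/JSON under ``out_dir``.
    Deterministic given the seed.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir or cfg.get("out_dir", "kinloss_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    table_paths = cfg.get("tables", {})
    missing = [t for t in _REQUIRED_TABLES if t not in table_paths]
    if missing:
        raise ConfigurationError(f"config missing input tables: {missing}")
    tables = {name: load_vital_table(path, name) for name, path in table_paths.items()}

    years_cfg = cfg.get("years", {})
    try:
        incidence_years = list(range(years_cfg["incidence"][0], years_cfg["incidence"][1] + 1))
        prevalence_years = list(range(years_cfg["prevalence"][0], years_cfg["prevalence"][1] + 1))
    except KeyError as e:
        raise ConfigurationError(f"config years missing {e}") from None
    have = set(tables["mortality"]["year"].unique())
    gaps = sorted(set(incidence_years) - have)
    if gaps:
        raise ConfigurationError(f"mortality table lacks incidence years {gaps}")

    n_rep = int(cfg.get("n_rep", 0))
    if n_rep >= 2 and "seed" not in cfg:
        raise ConfigurationError("replicate runs require an explicit seed")
    seed = int(cfg.get("seed", 0))
    mode = cfg.get("mode", "national")
    if mode != "national":
        raise ConfigurationError("run_pipeline currently drives the national mode; use estimate_state for state runs")

    est = pipeline.estimate_national(tables, incidence_years, prevalence_years)
    totals_runs = [component_totals(est)]

    if n_rep >= 2:
        rng = np.random.default_rng(seed)
        reps = {
            name: uncertainty.poisson_comonotone(tables[name], n_rep, rng)
            for name in ("mortality", "natality", "population")
        }
        for k in range(n_rep):
            rep_tables = dict(tables)
            for name in reps:
                t = tables[name].copy()
                t["count"] = reps[name][f"rep_{k}"].to_numpy(dtype=float)
                rep_tables[name] = t
            est_k = pipeline.estimate_national(rep_tables, incidence_years, prevalence_years)
            totals_runs.append(component_totals(est_k))
        totals_runs = totals_runs[1:]  # summarize over the replicate ensemble

    child_pop = child_population_by_year(tables["population"])
    change_pairs = [tuple(p) for p in cfg.get("change_pairs", [])]
    summary = build_summary(totals_runs, child_pop, change_pairs)

    artifacts = {
        "incidence": est["new_combined"],
        "incidence_by_sex": est["new_by_sex"],
        "prevalence": est["lifetime"],
        "caregiver_loss_incidence": est["L_new"],
        "caregiver_loss_prevalence": est["L_lifetime"],
        "totals": totals_runs[0],
        "summary": summary,
    }
    for name, df in artifacts.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    run_log = {
        "mode": mode,
        "seed": seed,
        "n_rep": n_rep,
        "incidence_years": [min(incidence_years), max(incidence_years)],
        "prevalence_years": [min(prevalence_years), max(prevalence_years)],
        "change_pairs": [list(p) for p in change_pairs],
        "quantile_method": "linear",
        "tables": {k: str(v) for k, v in table_paths.items()},
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    logger.info("pipeline artifacts written to %s", out_dir)
    return {"estimates": est, "summary": summary, "out_dir": out_dir}


def simulate_to_dir(sim_config: dict | str | Path, out_dir: str | Path) -> dict:
    """Generate synthetic vital tables (and exact truth) to CSV files."""
    cfg_dict = _load_config(sim_config) if not isinstance(sim_config, dict) else sim_config
    cfg = synthetic.SimConfig.from_dict(cfg_dict)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    linelist = synthetic.simulate_cohort(cfg)
    tables = synthetic.emit_vital_tables(linelist)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    truth = synthetic.true_kin_loss(linelist)
    truth.incidence_combined.to_csv(out_dir / "truth_incidence.csv", index=False)
    truth.prevalence_combined.to_csv(out_dir / "truth_prevalence.csv", index=False)
    return {"tables": tables, "truth": truth, "out_dir": out_dir}
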