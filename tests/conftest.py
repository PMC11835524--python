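"""Shared fixtures: session-scoped synthetic cohorts at three scales.

The small cohort drives unit and Monte Carlo consistency tests; the oracle
cohort (2e5 families) drives the microsimulation-equivalence checks; the
multi-state cohort drives suppression/rescaling tests.  All are seeded and
deterministic.
"""

from __future__ import annotations

import pandas as pd
import pytest

from kinloss.pipeline import (
    estimate_national,
    estimate_state,
    prepare_state_inputs,
)
from kinloss.synthetic import (
    SimConfig,
    emit_vital_tables,
    simulate_cohort,
    true_kin_loss,
)

ORACLE_INC_YEARS = list(range(1993, 2021))
ORACLE_PREV_YEARS = list(range(2010, 2021))


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(n_families=20_000, seed=42)
    linelist = simulate_cohort(cfg)
    tables = emit_vital_tables(linelist)
    return {"config": cfg, "linelist": linelist, "tables": tables}


@pytest.fixture(scope="session")
def small_est(small_sim):
    est = estimate_national(small_sim["tables"], ORACLE_INC_YEARS, ORACLE_PREV_YEARS)
    return est


@pytest.fixture(scope="session")
def oracle_run():
    cfg = SimConfig(n_families=400_000, seed=2024)
    linelist = simulate_cohort(cfg)
    tables = emit_vital_tables(linelist)
    est = estimate_national(tables, ORACLE_INC_YEARS, ORACLE_PREV_YEARS)
    truth = true_kin_loss(linelist, years=ORACLE_PREV_YEARS)
    return {
        "config": cfg,
        "tables": tables,
        "est": est,
        "truth": truth,
        "inc_years": ORACLE_INC_YEARS,
        "prev_years": ORACLE_PREV_YEARS,
    }


@pytest.fixture(scope="session")
def state_run():
    cfg = SimConfig(
        n_families=40_000,
        seed=5,
        state_weights={"A": 0.4, "B": 0.3, "C": 0.2, "D": 0.1},
    )
    linelist = simulate_cohort(cfg)
    national_tables = emit_vital_tables(linelist, by_state=False)
    state_tables = prepare_state_inputs(emit_vital_tables(linelist, by_state=True), suppress=True)
    inc_years = list(range(1998, 2021))
    prev_years = list(range(2015, 2021))
    res = estimate_state(state_tables, national_tables, inc_years, prev_years)
    return {
        "config": cfg,
        "linelist": linelist,
        "state_tables": state_tables,
        "national_tables": national_tables,
        "result": res,
        "inc_years": inc_years,
        "prev_years": prev_years,
    }


def tiny_linelist(individuals: list[dict], links: list[dict], roles: list[dict] | None = None, years=(2000, 2020)) -> "object":
    """Hand-built line list for worked examples (used by unit tests)."""
    from kinloss.synthetic import FamilyLineList

    cfg = SimConfig(n_families=1, years=years, seed=0)
    ind = pd.DataFrame(individuals)
    for col, default in (("state", "S1"), ("death_year", float("nan")), ("death_cause", None), ("family", 0), ("role", "child")):
        if col not in ind.columns:
            ind[col] = default
    lk = pd.DataFrame(links, columns=["child_id", "mother_id", "father_id"])
    gr = pd.DataFrame(roles or [], columns=["grandparent_id", "child_id", "role"])
    return FamilyLineList(ind, lk, gr, cfg)
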