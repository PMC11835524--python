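"""National trend summary with rates per 100 children and percent changes.

Runs the configuration-driven pipeline end to end on synthetic tables and
prints the trend summary: incidence and prevalence counts by component
(orphanhood, primary and secondary grandparent-caregiver loss), rates per
100 children, and the percent change over the last decade of the window.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from kinloss.reporting import run_pipeline, simulate_to_dir

with TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"
    simulate_to_dir({"n_families": 30_000, "seed": 3, "years": [1975, 2020]}, data)
    cfg = {
        "tables": {
            k: str(data / f"{k}.csv")
            for k in ("mortality", "natality", "population", "child_survival", "caregiver")
        },
        "years": {"incidence": [1993, 2020], "prevalence": [2010, 2020]},
        "seed": 1,
        "change_pairs": [[2010, 2020]],
    }
    out = run_pipeline(cfg, Path(tmp) / "out")

summary = out["summary"]
latest = summary[summary["year"] == 2020]
cols = ["measure", "component", "count", "rate_per_100", "change_2010_2020_pct"]
print(latest[cols].to_string(index=False, float_format=lambda v: f"{v:,.2f}"))
# Counts are children (incident = newly bereaved that year; prevalent =
# living children under 18 ever bereaved); rates divide by the year's child
# population.  Component rows sum to the de-duplicated total.
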