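"""Monte Carlo uncertainty: co-monotone Poisson replicates and intervals.

Draws a co-monotone Poisson replicate ensemble around a small mortality
series, shows that the coupling makes replicates consistently high or low
across years while leaving per-year marginals Poisson, and summarizes a
derived quantity (the 2002/2000 percent change) per replicate.
"""

import numpy as np
import pandas as pd

from kinloss.uncertainty import poisson_comonotone, summarize

counts = pd.DataFrame(
    {
        "year": [2000, 2001, 2002],
        "age_band": "35-39",
        "sex": "male",
        "race_ethnicity": "non-Hispanic white",
        "cause": "drug_overdose",
        "count": [400, 450, 520],
    }
)
ens = poisson_comonotone(counts, n_rep=1000, seed=11)
reps = ens.filter(like="rep_").to_numpy()

print("per-year replicate means vs counts:", np.round(reps.mean(axis=1), 1).tolist(),
      "vs", counts["count"].tolist())
corr = np.corrcoef(reps[0], reps[2])[0, 1]
print(f"cross-year replicate correlation (2000 vs 2002): {corr:.3f}")

# Derived quantities are computed per replicate before summarizing.
pct_change = 100.0 * (reps[2] / reps[0] - 1.0)
s = summarize(pct_change[None, :])
print(f"2000->2002 change: median {s['median'].iloc[0]:+.1f}% "
      f"(95% UI {s['lo95'].iloc[0]:+.1f}% to {s['hi95'].iloc[0]:+.1f}%)")
# Co-monotonization maximizes positive temporal dependence, so trend
# uncertainty is driven by level uncertainty rather than artificially
# cancelled by independent year-to-year noise.
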