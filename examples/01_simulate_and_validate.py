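"""Simulate a family cohort and validate the estimator against exact truth.

Builds a modest synthetic cohort (50,000 families over 1975-2020), emits the
aggregated vital-statistics tables the pipeline consumes, runs the national
orphanhood estimator, and compares its combined incidence and prevalence
against the exact counts enumerated from the family line list.
"""

from kinloss.pipeline import estimate_national
from kinloss.synthetic import SimConfig, emit_vital_tables, simulate_cohort, true_kin_loss

config = SimConfig(n_families=50_000, seed=7)
linelist = simulate_cohort(config)
tables = emit_vital_tables(linelist)

incidence_years = list(range(1993, 2021))
prevalence_years = list(range(2010, 2021))
est = estimate_national(tables, incidence_years, prevalence_years)
truth = true_kin_loss(linelist, years=prevalence_years)

est_inc = est["new_combined"].groupby("year")["new"].sum().loc[incidence_years]
true_inc = truth.incidence_combined.groupby("year")["count"].sum().loc[incidence_years]
est_prev = est["lifetime"].groupby("year")["lifetime"].sum()
true_prev = truth.prevalence_combined.groupby("year")["count"].sum()

print(f"cohort: {len(linelist.individuals):,} individuals, "
      f"{len(linelist.links):,} children, "
      f"{int(linelist.individuals['death_year'].notna().sum()):,} deaths")
print(f"combined incidence 1993-2020: estimated {est_inc.sum():,.0f} "
      f"vs true {true_inc.sum():,} "
      f"({100 * (est_inc.sum() / true_inc.sum() - 1):+.2f}%)")
for year in (2010, 2015, 2020):
    print(f"prevalence {year}: estimated {est_prev[year]:,.0f} "
          f"vs true {true_prev[year]:,} "
          f"({100 * (est_prev[year] / true_prev[year] - 1):+.2f}%)")
# The estimator sees only aggregated counts, never the family links; the
# gaps here are Monte Carlo noise at this modest cohort size (they fall to
# a few tenths of a percent at the 400,000-family validation scale used in
# the test suite), showing that the expected-children attribution and
# double-loss corrections recover the family-level truth.
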