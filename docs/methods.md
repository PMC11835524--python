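# Methods

`kinloss` estimates the incidence and prevalence of orphanhood (death of
one or both parents) and co-residing grandparent-caregiver loss among
children aged 0–17, from stratified vital-statistics count tables rather
than linked family records. This note describes the model, the numerical
choices, the synthetic-data generator used for validation, and the known
limitations.

## The estimation model

### Expected children per decedent

The estimator attributes to every decedent the expected number of living
children of each single age b = 0…17. For a parent of sex s, race/ethnicity
r and single age a dying in year y,

    C[y, a, s, r, b] = FR[y−b, band(a−b), s, r] × p_survive[y−b, b+1],

where FR is the fertility rate (births per person-year) of the natal age
band containing the parent's age a−b at the child's birth, and p_survive is
the probability that a child born in year y−b survived to age b+1. Ages with
a−b outside the reproductive range (mothers 15–49, fathers 15–77) contribute
zero, which bounds decedent ages at 15–66 for mothers and 15–94 for fathers.
Mortality counts come in 5-year bands (15–19 … 80–84, 85+), so band-level
expected counts are the mean of C over single ages within the band; the open
85+ band enumerates ages 85 up to the sex-specific maximum. Pediatric
survival is not stratified by race/ethnicity; the child hazards used for
prevalence accumulation are.

Fertility rates are the ratio of natality to population counts per year,
band, sex and race/ethnicity. Years before the earliest observed rate reuse
the earliest year's rates (historic extrapolation); a sensitivity mode
accepts observed earlier rates, which take precedence.

### Incidence and double-loss corrections

Expected bereavements per stratum are

    death_of_parent[y, a′, s, r, b, c] = C[y, a′, s, r, b] × D[y, a′, s, r, c],

with D the death count for cause c. Summing both parental sexes would count
twice the children who lose both parents, so two corrections are subtracted,
both assuming the other parent is of the same age band and race/ethnicity as
the decedent and that parental deaths are independent:

* same-year double loss: the other parent's annual death probability times
  death_of_parent, averaged over the two sexes' (non-identical) estimates;
* prior-year loss: the cumulative probability that the other parent died in
  any of the previous 1…b−1 years, capped at 1, times death_of_parent. Per
  lag i the annual probabilities at the lagged band containing a−i are
  averaged over the five single ages a of the decedent's band (lagged ages
  below 15 carry zero hazard).

Combined incidence is floored at zero with a logged warning. By-sex
incidence subtracts only the prior-year term, so maternal and paternal
series each include children losing both parents in the same year.

**Hazard scale.** Band hazards are stored as the life-table mid-band form
ₙh_x = D/(nP), algebraically equal to (1/n)·2q/(2−q) with q = D/(P + D/2).
This is a density per year of age; the probability that a band member dies
within the calendar year — the quantity the corrections are defined on — is
n·ₙh_x = D/P (capped at 1), and that is what `incidence_components` uses.
Using ₙh_x itself would leave roughly four fifths of the true double-orphan
overlap uncorrected; on the microsimulation oracle that misstatement is
directly visible as a ~3% overestimate of combined incidence, while the
annual-probability form is unbiased. With US-like adult hazards the two
corrections together amount to ~4% of death_of_parent totals.

All-cause hazards are used for the other parent regardless of the
decedent's cause category. The exact lag-indexing of the prior-year term is
ambiguous in band notation; the reading above (lag both the year and the
band, average over the band's single ages) is a documented choice.

### Prevalence

Prevalent (lifetime) counts accrue incidence over the current and previous
17 years while discounting for child mortality and dropping cohorts that
aged past 17:

    lifetime[y, r, b, c] = Σ_{i=0..b} new[y−i, r, b−i, c] × Π_{j=1..i} (1 − h1[y−j, r, b−j]),

with h1 the single-age child hazard. The product starts at j = 1 because
incidence already conditions on survival through the year of loss.

### Grandparent-caregiver loss

Survey co-residence data provide, per year: the sex-specific share γ of
adults 30+ living with grandchildren, a race share multiplier, the
proportion p_mr providing most of the grandchildren's basic needs, and the
skip-generation share q_sg among those. Their products split co-residing
caregivers into three exhaustive types (skip-generation,
most-responsible-not-skip-gen, co-residing-not-most-responsible); the first
two are primary caregivers, the third secondary. Each caregiver death
leaves a minimum of one child behind, so

    G^x[y, s, r, c] = γ^x[y, s, r] × Σ_{a′ ≥ 30} D[y, a′, s, r, c]

is a lower bound. Years before the earliest survey year reuse that year's
proportions. Child-age disaggregation borrows the age composition of
children losing parents aged 30+ (cause-specific by default; an all-cause
pooled mode and external survey weights are available); strata with
all-zero composition fall back to uniform weights with a warning.

Combined caregiver loss de-duplicates children counted under both parental
and grandparent loss: fixed shares of grandchildren whose parents had
already died (11% for skip-generation and for the absent parent of
single-parent households; 70% of non-skip-generation grandchildren co-reside
with both parents) are removed, and a half-year exposure to the
parent-age-weighted mortality rates h_M, h_F discounts for parents dying
after the survey reference point:

    G_dedup = G_sg (1 − 0.11)(1 − (h_M + h_F − h_M h_F)/2)
            + (G_mrnsg + G_conmr)(0.70 + 0.30 × 0.89)(1 − (h_M + h_F − h_M h_F)/2).

Caregiver-loss prevalence adds accumulated G_dedup contributions to
orphanhood prevalence; here the survival product starts at j = 0 (the
cross-sectional grandparent contributions do not already condition on the
child surviving the loss year). Whether the j = 0 start is intentional in
the source method is unclear; it is implemented as stated.

### Cause and race harmonization

Deaths arrive under ICD-9 (282-recode) or ICD-10 (113-recode) source codes
and are mapped to 53 rankable caregiver-loss causes plus a residual
``other``; drug-overdose sub-codes (ICD-10 X40–X44, X60–X64, X85, Y10–Y14
and their ICD-9 counterparts) are pulled out of suicide, homicide and
unintentional injury into a dedicated drug-overdose category, and the map
loader rejects any mapping that violates this. Mapping conserves totals per
stratum exactly. ICD-9-era counts are multiplied by cause-specific
comparability ratios (absent ratios default to 1); counts are real-valued
downstream with no re-rounding. Race and Hispanic origin reporting is
standardized to five categories, Hispanic origin taking precedence;
more-than-one-race records are excluded with a logged count. A year lacking
race reporting can be redistributed using an adjacent year's composition
per (band, sex, cause).

### State-level estimation

Public state tabulations suppress counts below 10, so state estimation runs
unstratified by race and in two correction stages. Suppressed cells are
imputed with 2 (1 in state-by-race mode), then state mortality is rescaled
so state sums match national counts per (year, band, sex, cause) — the η
factors; strata suppressed in every state keep η = 1 with an audit flag.
After per-state estimation, correction factors ν per (year, sex, cause) —
deliberately not age-specific — align summed state incidence with the
national estimate; because ν is computed and applied at the same
granularity, post-correction agreement is exact up to floating point, well
within the 0.5% bound the method targets. Fertility series with missing
years are filled by tricube-weighted local linear regression (LOESS, span
0.85, via statsmodels lowess); trailing gaps carry the last observed value;
series with fewer than 4 observed points fall back to carry-forward.
Reliability screens exclude (state, race) strata with more than two age
bands under 20 births, analogously for deaths, and states whose race-summed
incidence falls more than 20% below the state estimate.

### Uncertainty

Uncertainty is phenomenological: 1,000 (configurable) Poisson replicates
are drawn around every mortality, natality and population count and
co-monotonized across years within each stratum — the n draws per cell are
sorted and replicate k takes the k-th order statistic in every year — which
maximizes positive temporal dependence without altering any per-cell
marginal distribution. Co-monotonization couples years only, not strata.
Comparability ratios and survey proportions are resampled from normal
distributions (90% margins of error divided by 1.645; draws truncated at
zero). The pipeline is re-run per replicate and 2.5/50/97.5% quantiles are
taken pointwise using linear interpolation between order statistics
(declared in output metadata). Derived quantities — rates, percent
changes — are computed per replicate before summarizing, so interval
endpoints of a change column are quantiles of per-replicate changes; the
change of medians is reported alongside for transparency.

## The synthetic-data generator and the oracle

The microsimulation draws families (one mother, one father, children, and
for 55% of families a grandparent) on an annual grid over 1975–2020.
Defaults are broadly US-like: a female fertility schedule peaking at 0.11
births per woman-year at 25–29; adult band hazards rising from 5×10⁻⁴
(15–19) to 0.15 (85+), males scaled by 1.6; child hazards of 6×10⁻³ in
infancy falling to 2×10⁻⁴ in mid-childhood; a five-cause death mix with 8%
drug overdose; three race/ethnicity groups (60/20/20). Within a year,
births precede deaths. Adult death years are drawn before births so the
dampened-fertility coupling mode (fertility tapering to zero or half over
an onset horizon before a parent's death) can condition on them; in the
central mode fertility and mortality are independent, matching the
estimator's assumption.

Several generator choices exist specifically so that the emitted aggregate
tables satisfy the estimator's assumptions, making the enumerated line-list
truth a valid oracle:

* every individual of the same age band, sex and race carries the same
  mortality hazard, so expected-children attribution from population rates
  is unbiased for the decedent subpopulation;
* fathers are 0–5 years older than their partner, which (a) approximates
  the estimator's same-band assumption for the other parent and (b) ends
  the male fertility support exactly at the 50–54 natal band boundary — a
  mid-band cutoff would hand old male decedents phantom expected children
  through the band-constant fertility assumption;
* grandparents are full members of the demographic frame from age 15
  (population denominators and hazards at every age). Admitting them only
  at older ages hands their deaths the undiluted fertility of bands they
  never belonged to and biases incidence upward by several percent;
* population tables are annual exposure counts (alive during the year,
  including same-year decedents), so emitted fertility and hazard rates are
  exact for the generating Bernoulli process.

Because the population frame contains never-bearing adults (grandparents),
the population-level fertility rate sits below the couple-level schedule —
as real denominators do; the generator's schedule is recovered against the
at-risk mothers. Children aging past 17 leave the frame; the parent
generation is the demographic universe for adult rates.

The truth tables are exact enumerations: combined incidence counts each
child once at the first qualifying parental death (a same-year double loss
is attributed to the mother's cause); maternal and paternal incidence each
count children losing both parents; prevalence counts children under 18
alive at the end of the year who ever experienced the loss; a child dying
in the year of the loss counts in incidence but never in later prevalence.

What passing oracle tests show — and what they do not: agreement within a
fraction of a percent (summed over 28 years at 4×10⁵ families)
demonstrates that the attribution, corrections and aging/survival
accumulation are mutually consistent and unbiased *when the model's
assumptions hold*. The generator deliberately satisfies those assumptions;
real populations do not (couple ages correlate beyond bands, fertility and
mortality correlate across socioeconomic strata, race/ethnicity of parent
and child can differ), so oracle agreement bounds implementation error, not
real-world bias. The dampened-fertility mode quantifies one such violation:
with fertility suppressed up to 3 years before death, the central estimator
overestimates incidence and the dampened sensitivity variant shrinks the
gap, directionally consistent with the source method's sensitivity
analysis.

Per-year incidence comparisons at this cohort size carry ~4–5% binomial
noise in the oracle itself (roughly 500 events per year), so per-year
checks are bounded by 2% plus three binomial standard errors of the yearly
truth count; the systematic (summed) deviation is held to 2%.

For the suppression-recovery property, a large-population multi-state
dataset is built by scaling natality/population deterministically and
redrawing adult mortality cells as Poisson variables around smooth expected
values (pooled rates × population), so cell expectations range continuously
across the suppression threshold, as in real public tables. In that regime
the imputation + rescaling machinery recovers unsuppressed-input state
incidence within 5% for every (state, cause) stratum passing the
small-death-counts reliability screen — and the strata that fail recovery
are exactly the screened-out ones, which is the screen's purpose. At raw
microsimulation scale nearly all cause-level parent-age cells fall below
the threshold and no stratum passes the screen; suppression adjustment
cannot (and is not claimed to) recover such data.

## Numerical choices and degenerate inputs

* Band midpoints are (lo + hi + 1)/2 for closed bands and 87.5 for 85+.
* Duplicate stratum keys are schema errors, never silently summed.
* Suppressed cells carry a flag and no count; flags survive imputation for
  audit.
* Division guards: zero population with positive births is an estimation
  error; with zero births the rate is 0 with a warning. Hazards are clipped
  to [0, 1] with a warning. In non-strict (pipeline) mode, mortality strata
  whose population emptied out within a year are dropped with a warning.
* The cumulative prior-loss probability and all probability-like draws are
  capped/truncated at their natural bounds.
* The dampened-fertility taper is a logistic in years-to-death (scale 0.5
  years, configurable), renormalized so the endpoints are exact: the floor
  at death, 1 at and beyond the onset. Only the endpoints are identified by
  the source method; the shape is a convention.
* Incidence floored at 0 with a warning rather than returning negative
  corrected counts.
* Missing hazard or incidence history raises an estimation error rather
  than extrapolating; years the caller declares computed count as true
  zeros when absent from sparse small-area data.

## Limitations

* The de-duplication constants (11%, 11%, 70%) are fixed point estimates;
  their uncertainty is not propagated beyond the normal resampling of the
  survey proportions.
* One child per grandparent caregiver is a floor; sibling groups make true
  grandparent-caregiver loss larger.
* The same-band/same-race assumption for the other parent understates the
  prior-loss correction when fathers are systematically older than the
  band width.
* State estimates inherit whatever bias suppression imputation leaves in
  heavily suppressed strata; the reliability screens bound, but do not
  remove, that bias.
* The replicate ensemble couples years, not strata; cross-stratum
  dependence (e.g. shared registration shocks) is not modeled.
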