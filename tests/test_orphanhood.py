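"""Core estimator: expected children, hazards, incidence, prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinloss import orphanhood
from kinloss.errors import EstimationError
from kinloss.fertility import FertilityLookup
from kinloss.orphanhood import (
    accumulate_prevalence,
    combine_incidence,
    expected_children,
    hazard_from_q,
    incidence_components,
    mortality_hazard,
)


class TestHazardIdentity:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.integers(0, 10_000),
        st.integers(1, 10_000_000),
        st.sampled_from([1, 5]),
    )
    def test_life_table_form_equals_ratio_form(self, D, P, n):
        """(1/n)*2q/(2-q) with q = D/(P + D/2) is algebraically D/(nP)."""
        if D >= P:
            D = P - 1
        if D < 0:
            return
        lhs = hazard_from_q(D, P, n)
        rhs = D / (n * P)
        if rhs > 0:
            assert abs(lhs - rhs) / rhs <= 1e-12
        else:
            assert lhs == 0.0


def _counts(year=2000, band="30-34", sex="female", race="Hispanic", count=10, cause=None):
    row = {"year": [year], "age_band": [band], "sex": [sex], "race_ethnicity": [race], "count": [count]}
    if cause is not None:
        row["cause"] = [cause]
    return pd.DataFrame(row)


class TestMortalityHazard:
    def test_adult_band_hazard(self):
        out = mortality_hazard(_counts(count=10), _counts(count=1000))
        assert out["hazard"].iloc[0] == pytest.approx(0.002)
        assert out["n"].iloc[0] == 5

    def test_no_deaths_zero_hazard(self):
        out = mortality_hazard(_counts(count=0), _counts(count=1000))
        assert out["hazard"].iloc[0] == 0.0

    def test_child_single_age_ratio(self):
        out = mortality_hazard(
            _counts(band="3", count=5), _counts(band="3", count=500)
        )
        assert out["hazard"].iloc[0] == pytest.approx(0.01)
        assert out["n"].iloc[0] == 1

    def test_zero_population_errors_when_strict(self):
        with pytest.raises(EstimationError):
            mortality_hazard(_counts(count=5), _counts(count=0))

    def test_open_band_midpoint(self):
        out = mortality_hazard(_counts(band="85+", count=1), _counts(band="85+", count=100))
        assert out["midpoint"].iloc[0] == 87.5


def _fert_table(rate_by_band, years, sex="female", race="Hispanic"):
    rows = []
    for y in years:
        for band, r in rate_by_band.items():
            rows.append({"year": y, "age_band": band, "sex": sex, "race_ethnicity": race, "rate": r})
    return pd.DataFrame(rows)


def _survival(years, p=0.99):
    return pd.DataFrame(
        [{"birth_year": y, "age": b, "p_survive": p} for y in years for b in range(18)]
    )


class TestExpectedChildren:
    def test_direct_product_of_rate_and_survival(self):
        fert = _fert_table({"20-24": 0.1}, years=range(1980, 2001))
        surv = _survival(range(1980, 2001), p=0.99)
        C = expected_children(FertilityLookup(fert), surv, years=[2000], races=["Hispanic"])
        # A 20-24-year-old mother with a newborn: all five single ages use
        # the 20-24 rate, so the band mean is exactly 0.1 x 0.99.
        cell = C[(C.age_band == "20-24") & (C.sex == "female") & (C.child_age == 0)]
        assert cell["expected_children"].iloc[0] == pytest.approx(0.099)

    def test_parent_too_young_at_birth_contributes_zero(self):
        fert = _fert_table({"15-19": 0.1, "20-24": 0.1}, years=range(1980, 2001))
        surv = _survival(range(1980, 2001))
        C = expected_children(FertilityLookup(fert), surv, years=[2000], races=["Hispanic"])
        # Mothers in 20-24 cannot have a 10-year-old (a - b < 15 for all a).
        cell = C[(C.age_band == "20-24") & (C.sex == "female") & (C.child_age == 10)]
        assert cell["expected_children"].iloc[0] == 0.0

    def test_band_attribution_uses_band_containing_lagged_age(self):
        # A 33-year-old with a 10-year-old was 23 at the birth: the 20-24
        # band rate applies, not the 30-34 one.
        fert = _fert_table({"20-24": 0.2, "30-34": 0.05}, years=range(1980, 2001))
        surv = _survival(range(1980, 2001), p=1.0)
        C = expected_children(FertilityLookup(fert), surv, years=[2000], races=["Hispanic"])
        cell = C[(C.age_band == "30-34") & (C.sex == "female") & (C.child_age == 10)]
        # Ages 30-34 lagged by 10 are 20-24: all five single ages use 0.2.
        assert cell["expected_children"].iloc[0] == pytest.approx(0.2)

    def test_missing_survival_cohort_errors(self):
        fert = _fert_table({"20-24": 0.1}, years=range(1980, 2001))
        surv = _survival(range(1999, 2001))
        with pytest.raises(EstimationError):
            expected_children(FertilityLookup(fert), surv, years=[2000], races=["Hispanic"])


def _hazard_table(h, years, bands_=("15-19", "20-24", "25-29", "30-34", "35-39", "40-44"), races=("Hispanic",)):
    rows = []
    for y in years:
        for sex in ("female", "male"):
            for race in races:
                for b in bands_:
                    rows.append(
                        {"year": y, "age_band": b, "sex": sex, "race_ethnicity": race, "n": 5, "midpoint": 0.0, "hazard": h}
                    )
    return pd.DataFrame(rows)


def _C_table(value, years, band="30-34", races=("Hispanic",)):
    rows = []
    for y in years:
        for sex in ("female", "male"):
            for race in races:
                for b in range(18):
                    rows.append(
                        {"year": y, "age_band": band, "sex": sex, "race_ethnicity": race, "child_age": b, "expected_children": value}
                    )
    return pd.DataFrame(rows)


class TestIncidenceComponents:
    def test_death_of_parent_is_expected_children_times_deaths(self):
        C = _C_table(0.5, [2000])
        deaths = _counts(count=200, cause="other")
        hz = _hazard_table(0.0, range(1984, 2001))
        comp = incidence_components(C, deaths, hz)
        assert np.allclose(comp["death_of_parent"], 100.0)

    def test_zero_opposite_hazard_kills_corrections(self):
        C = _C_table(0.5, [2000])
        deaths = _counts(count=200, cause="other")
        comp = incidence_components(C, deaths, _hazard_table(0.0, range(1984, 2001)))
        assert np.allclose(comp["new_double"], 0.0)
        assert np.allclose(comp["previous"], 0.0)

    def test_same_year_double_uses_annual_probability(self):
        # Band hazard 5h = 0.002 means an annual death probability of
        # 5 x 0.002 = 0.01 for the other parent; with 100 expected
        # bereavements the same-year double-loss term is 1.0.
        C = _C_table(0.5, [2000])
        deaths = _counts(count=200, cause="other")
        comp = incidence_components(C, deaths, _hazard_table(0.002, range(1984, 2001)))
        b0 = comp[(comp.child_age == 0) & (comp.sex == "female")]
        assert b0["new_double"].iloc[0] == pytest.approx(1.0)
        assert b0["previous"].iloc[0] == 0.0  # no prior years at b = 0

    def test_previous_accumulates_lagged_annual_probabilities(self):
        C = _C_table(0.5, [2000])
        deaths = _counts(count=200, cause="other")
        comp = incidence_components(C, deaths, _hazard_table(0.002, range(1984, 2001)))
        # For child age b the other parent could die in any of b-1 prior
        # years, each with annual probability 0.01 at every lagged band.
        for b in (1, 2, 5):
            row = comp[(comp.child_age == b) & (comp.sex == "female")]
            assert row["previous"].iloc[0] == pytest.approx(100.0 * 0.01 * (b - 1))

    def test_missing_hazard_history_errors(self):
        C = _C_table(0.5, [2000])
        deaths = _counts(count=200, cause="other")
        with pytest.raises(EstimationError):
            incidence_components(C, deaths, _hazard_table(0.002, [2000]))


class TestCombineIncidence:
    def _components(self, dopF=100.0, dopM=100.0, ndF=0.0, ndM=0.0, prevF=0.0, prevM=0.0):
        rows = []
        for sex, dop, nd, prev in (("female", dopF, ndF, prevF), ("male", dopM, ndM, prevM)):
            rows.append(
                {
                    "year": 2000, "age_band": "30-34", "sex": sex, "race_ethnicity": "Hispanic",
                    "child_age": 0, "cause": "other",
                    "death_of_parent": dop, "new_double": nd, "previous": prev,
                }
            )
        return pd.DataFrame(rows)

    def test_no_corrections_sums_both_sexes(self):
        combined, _ = combine_incidence(self._components())
        assert combined["new"].iloc[0] == pytest.approx(200.0)

    def test_average_of_double_terms_subtracted(self):
        combined, _ = combine_incidence(self._components(ndF=0.4, ndM=0.2))
        assert combined["new"].iloc[0] == pytest.approx(200.0 - 0.3)

    def test_by_sex_subtracts_previous_only(self):
        _, by_sex = combine_incidence(self._components(dopM=100.0, prevM=1.0))
        male = by_sex[by_sex.sex == "male"]
        assert male["new"].iloc[0] == pytest.approx(99.0)

    def test_by_sex_minus_combined_equals_mean_double(self):
        # Consistency of the by-sex and combined definitions: the by-sex
        # totals exceed the combined total by the subtracted average
        # same-year double-loss term.
        comp = self._components(ndF=0.4, ndM=0.2, prevF=1.0, prevM=2.0)
        combined, by_sex = combine_incidence(comp)
        gap = by_sex["new"].sum() - combined["new"].sum()
        assert gap == pytest.approx((0.4 + 0.2) / 2)

    def test_negative_corrected_incidence_floored(self, caplog):
        combined, _ = combine_incidence(self._components(dopF=0.1, dopM=0.0, prevF=1.0))
        assert combined["new"].iloc[0] == 0.0


def _child_hazards(h, years, races=("Hispanic",)):
    return pd.DataFrame(
        [
            {"year": y, "age": b, "race_ethnicity": r, "hazard": h}
            for y in years
            for b in range(18)
            for r in races
        ]
    )


def _new_table(entries):
    """entries: list of (year, child_age, value)."""
    return pd.DataFrame(
        [
            {"year": y, "age_band": "30-34", "race_ethnicity": "Hispanic", "child_age": b, "cause": "other", "new": v}
            for y, b, v in entries
        ]
    )


class TestPrevalence:
    def test_pure_accrual_without_child_mortality(self):
        new = _new_table([(2000, 0, 100.0), (2001, 0, 100.0), (2002, 0, 100.0)])
        out = accumulate_prevalence(
            new, _child_hazards(0.0, range(1980, 2003)), years=[2002],
            computed_years=list(range(1985, 2003)),
        )
        vals = out.set_index("child_age")["lifetime"]
        assert vals.loc[0] == pytest.approx(100.0)
        assert vals.loc[1] == pytest.approx(100.0)
        assert vals.loc[2] == pytest.approx(100.0)
        assert vals.loc[3] == 0.0

    def test_child_hazard_one_leaves_only_current_year(self):
        new = _new_table([(2000, 0, 100.0), (2001, 0, 100.0), (2002, 0, 100.0)])
        out = accumulate_prevalence(
            new, _child_hazards(1.0, range(1980, 2003)), years=[2002],
            computed_years=list(range(1985, 2003)),
        )
        vals = out.set_index("child_age")["lifetime"]
        assert vals.loc[0] == pytest.approx(100.0)
        assert vals.loc[1] == 0.0

    def test_single_cohort_survival_discount(self):
        # 100 children newly bereaved at age 0 in 2000 with 1% annual child
        # mortality are 100 x 0.99^2 = 98.01 prevalent two years later.
        new = _new_table([(2000, 0, 100.0)])
        out = accumulate_prevalence(
            new, _child_hazards(0.01, range(1980, 2003)), years=[2002],
            computed_years=list(range(1985, 2003)),
        )
        vals = out.set_index("child_age")["lifetime"]
        assert vals.loc[2] == pytest.approx(100.0 * 0.99**2)

    def test_incomplete_history_errors(self):
        new = _new_table([(2002, 0, 100.0)])
        with pytest.raises(EstimationError):
            accumulate_prevalence(new, _child_hazards(0.0, range(1980, 2003)), years=[2002])

    def test_telescoping_with_zero_child_mortality(self):
        # With no child mortality, prevalence this year equals last year's
        # prevalence shifted one age (dropping those who turned 18) plus
        # this year's incidence.
        entries = [(y, b, float((y - 1990) * 18 + b + 1)) for y in range(1990, 2011) for b in range(18)]
        new = _new_table(entries)
        hz = _child_hazards(0.0, range(1985, 2011))
        out = accumulate_prevalence(new, hz, years=[2009, 2010], computed_years=list(range(1990, 2011)))
        prev = out.pivot_table(index="child_age", columns="year", values="lifetime")
        inc_2010 = new[new.year == 2010].set_index("child_age")["new"]
        for b in range(1, 18):
            expected = prev.loc[b - 1, 2009] + inc_2010.loc[b]
            assert prev.loc[b, 2010] == pytest.approx(expected)


class TestCorrectionsAreSmall:
    def test_double_loss_corrections_below_five_percent(self, small_est):
        comp = small_est["components"]
        share = (comp["new_double"].sum() + comp["previous"].sum()) / comp["death_of_parent"].sum()
        assert 0 < share <= 0.05
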