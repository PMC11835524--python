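"""Grandparent-caregiver loss: proportions, incidence, de-duplication,
age disaggregation and combined caregiver prevalence."""

import numpy as np
import pandas as pd
import pytest

from kinloss.errors import ConfigurationError, EstimationError
from kinloss.grandparents import (
    CAREGIVER_TYPES,
    DedupParams,
    caregiver_prevalence,
    caregiver_proportions,
    dedup_caregiver,
    disaggregate_child_age,
    grandparent_incidence,
    parent_hazard_aggregate,
    proportions_for_year,
)


def _acs(year=2010, gamma=0.04, p_race=0.5, p_mr=0.2, q_sg=0.3):
    rows = []
    for sex in ("female", "male"):
        rows.append(
            {
                "year": year, "sex": sex, "race_ethnicity": "Hispanic",
                "gamma_coreside": gamma, "p_coreside_race": p_race,
                "p_most_responsible": p_mr, "q_skip_gen": q_sg,
            }
        )
    return pd.DataFrame(rows)


class TestProportions:
    def test_skip_gen_product(self):
        props = caregiver_proportions(_acs())
        assert props["gamma_skip_gen"].iloc[0] == pytest.approx(0.04 * 0.5 * 0.2 * 0.3)

    def test_three_types_sum_to_coreside_share(self):
        props = caregiver_proportions(_acs())
        total = (
            props["gamma_skip_gen"]
            + props["gamma_most_responsible_not_sg"]
            + props["gamma_co_reside_not_mr"]
        )
        # Algebraic identity: p*q + p*(1-q) + (1-p) = 1.
        assert np.allclose(total, 0.04 * 0.5)

    def test_years_before_survey_fall_back_to_earliest(self):
        props = caregiver_proportions(_acs(year=2010))
        rows = proportions_for_year(props, 2005)
        assert (rows["year"] == 2005).all()
        assert rows["gamma_skip_gen"].iloc[0] == pytest.approx(0.04 * 0.5 * 0.2 * 0.3)

    def test_proportion_outside_unit_interval_rejected(self):
        bad = _acs(gamma=1.2)
        with pytest.raises(ConfigurationError):
            caregiver_proportions(bad)


def _deaths30(count=10_000, year=2010, band="55-59"):
    return pd.DataFrame(
        {
            "year": [year], "age_band": [band], "sex": ["female"],
            "race_ethnicity": ["Hispanic"], "cause": ["other"], "count": [count],
        }
    )


class TestGrandparentIncidence:
    def test_one_child_per_decedent_times_gamma(self):
        props = caregiver_proportions(_acs(gamma=0.02, p_race=0.1, p_mr=0.5, q_sg=1.0))
        # gamma_skip_gen = 0.001 exactly.
        G = grandparent_incidence(props, _deaths30(10_000))
        assert G["G_skip_gen"].iloc[0] == pytest.approx(10.0)

    def test_primary_is_sum_of_its_two_types(self, small_est):
        G = small_est["G"]
        assert np.allclose(G["G_primary"], G["G_skip_gen"] + G["G_most_responsible_not_sg"])

    def test_zero_gamma_zero_loss(self):
        props = caregiver_proportions(_acs(gamma=0.0))
        G = grandparent_incidence(props, _deaths30())
        assert (G[[f"G_{x}" for x in CAREGIVER_TYPES]] == 0).all().all()

    def test_deaths_under_30_rejected(self):
        props = caregiver_proportions(_acs())
        with pytest.raises(EstimationError):
            grandparent_incidence(props, _deaths30(band="25-29"))

    def test_total_loss_never_exceeds_coreside_share_of_deaths(self, small_sim, small_est):
        # One-child-per-grandparent floor: total grandparent-loss incidence
        # is bounded by total 30+ deaths times the largest co-residence
        # proportion.
        from kinloss import bands
        from kinloss.pipeline import split_child_strata

        G = small_est["G"]
        total = (G["G_primary"] + G["G_secondary"]).sum()
        adult_deaths, _ = split_child_strata(small_sim["tables"]["mortality"])
        lo = adult_deaths["age_band"].map(lambda b: bands.parse_band(b)[0])
        deaths30 = adult_deaths[(lo >= 30) & adult_deaths["year"].isin(G["year"].unique())]["count"].sum()
        props = small_est["caregiver_proportions"]
        gamma_max = (props["gamma_coreside"] * props["p_coreside_race"]).max()
        assert total <= gamma_max * deaths30


class TestDisaggregation:
    def _G(self):
        return pd.DataFrame(
            {
                "year": [2010], "sex": ["female"], "race_ethnicity": ["Hispanic"], "cause": ["other"],
                "G_skip_gen": [18.0], "G_most_responsible_not_sg": [0.0], "G_co_reside_not_mr": [0.0],
                "G_primary": [18.0], "G_secondary": [0.0],
            }
        )

    def test_uniform_composition_splits_evenly(self):
        comp = pd.DataFrame(
            {
                "sex": "female", "race_ethnicity": "Hispanic", "cause": "other",
                "child_age": range(18), "weight": 1 / 18,
            }
        )
        out = disaggregate_child_age(self._G(), comp)
        assert np.allclose(out["G_skip_gen"], 1.0)

    def test_point_mass_composition(self):
        comp = pd.DataFrame(
            {
                "sex": ["female"], "race_ethnicity": ["Hispanic"], "cause": ["other"],
                "child_age": [17], "weight": [1.0],
            }
        )
        out = disaggregate_child_age(self._G(), comp)
        assert out["G_skip_gen"].sum() == pytest.approx(18.0)
        assert set(out["child_age"]) == {17}

    def test_totals_conserved_over_child_ages(self, small_est):
        G, G_by_age = small_est["G"], small_est["G_dedup"]
        keys = ["year", "sex", "race_ethnicity", "cause"]
        before = G.set_index(keys)["G_primary"].sort_index()
        after = G_by_age.groupby(keys)["G_primary"].sum().sort_index()
        pd.testing.assert_series_equal(before, after, check_exact=False, rtol=1e-9)

    def test_all_cause_mode_pools_numerator(self, small_est):
        from kinloss.grandparents import orphanhood_age_composition

        comp = orphanhood_age_composition(small_est["components"], mode="all_cause")
        assert "cause" not in comp.columns
        sums = comp.groupby(["sex", "race_ethnicity"])["weight"].sum()
        assert np.allclose(sums, 1.0)


class TestDedup:
    def _G_row(self, skip=100.0, mr=0.0, co=0.0):
        return pd.DataFrame(
            {
                "year": [2010], "sex": ["female"], "race_ethnicity": ["Hispanic"], "cause": ["other"],
                "G_skip_gen": [skip], "G_most_responsible_not_sg": [mr], "G_co_reside_not_mr": [co],
                "G_primary": [skip + mr], "G_secondary": [co],
            }
        )

    def _hazards(self, h=0.01):
        return pd.DataFrame(
            {
                "year": [2010, 2010], "sex": ["female", "male"],
                "race_ethnicity": ["Hispanic", "Hispanic"], "h_parent": [h, h],
            }
        )

    def test_worked_value_against_brute_force(self):
        # Independent evaluation: G_skip = 100, p_skip_died = 0.11,
        # h_M = h_F = 0.01, six-month exposure:
        expected = 100.0 * (1 - 0.11) * (1 - (0.01 + 0.01 - 0.01 * 0.01) * 0.5)
        out = dedup_caregiver(self._G_row(), self._hazards(0.01))
        assert out["G_dedup"].iloc[0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(88.11445, abs=1e-9)

    def test_identity_when_probabilities_and_hazards_zero(self):
        params = DedupParams(0.0, 0.0, 1.0, 0.5)
        out = dedup_caregiver(self._G_row(50.0, 30.0, 20.0), self._hazards(0.0), params)
        assert out["G_dedup"].iloc[0] == pytest.approx(100.0)

    def test_defaults_loaded_when_unspecified(self):
        p = DedupParams()
        assert (p.p_skip_gen_parent_died, p.p_other_parent_died, p.p_both_parents_present) == (0.11, 0.11, 0.70)

    def test_monotone_decreasing_in_dedup_inputs(self):
        base = dedup_caregiver(self._G_row(50.0, 30.0, 20.0), self._hazards(0.01))["G_dedup"].iloc[0]
        higher_p = dedup_caregiver(
            self._G_row(50.0, 30.0, 20.0), self._hazards(0.01), DedupParams(p_skip_gen_parent_died=0.2)
        )["G_dedup"].iloc[0]
        higher_h = dedup_caregiver(self._G_row(50.0, 30.0, 20.0), self._hazards(0.05))["G_dedup"].iloc[0]
        assert higher_p < base
        assert higher_h < base

    def test_dedup_bounded_by_raw_total(self, small_est):
        G = small_est["G_dedup"]
        assert (G["G_dedup"] <= G["G_primary"] + G["G_secondary"] + 1e-12).all()

    def test_missing_hazards_rejected(self):
        with pytest.raises(EstimationError):
            dedup_caregiver(self._G_row(), self._hazards().assign(year=1999))


class TestParentHazardAggregate:
    def _rates(self, rates_by_band):
        return pd.DataFrame(
            [
                {"year": 2010, "age_band": b, "sex": "female", "race_ethnicity": "Hispanic", "rate": r}
                for b, r in rates_by_band.items()
            ]
        )

    def test_point_weight_returns_that_rate(self):
        rates = self._rates({"25-29": 0.01, "30-34": 0.03})
        weights = pd.DataFrame({"age_band": ["30-34"], "weight": [1.0]})
        out = parent_hazard_aggregate(rates, weights)
        assert out["h_parent"].iloc[0] == pytest.approx(0.03)

    def test_equal_weights_mean(self):
        rates = self._rates({"25-29": 0.01, "30-34": 0.03})
        weights = pd.DataFrame({"age_band": ["25-29", "30-34"], "weight": [0.5, 0.5]})
        out = parent_hazard_aggregate(rates, weights)
        assert out["h_parent"].iloc[0] == pytest.approx(0.02)

    def test_zero_rates_zero_aggregate(self):
        rates = self._rates({"25-29": 0.0, "30-34": 0.0})
        weights = pd.DataFrame({"age_band": ["25-29", "30-34"], "weight": [0.5, 0.5]})
        assert parent_hazard_aggregate(rates, weights)["h_parent"].iloc[0] == 0.0

    def test_weights_not_summing_to_one_rejected(self):
        rates = self._rates({"25-29": 0.01, "30-34": 0.03})
        weights = pd.DataFrame({"age_band": ["25-29", "30-34"], "weight": [0.5, 0.6]})
        with pytest.raises(ConfigurationError):
            parent_hazard_aggregate(rates, weights)


class TestCaregiverPrevalence:
    def _child_hazards(self, h, years):
        return pd.DataFrame(
            [
                {"year": y, "age": b, "race_ethnicity": "Hispanic", "hazard": h}
                for y in years
                for b in range(18)
            ]
        )

    def _O_lifetime(self, years):
        return pd.DataFrame(
            [
                {"year": y, "sex": "female", "race_ethnicity": "Hispanic", "child_age": b, "cause": "other", "lifetime": 7.0}
                for y in years
                for b in range(18)
            ]
        )

    def _G_dedup(self, entries, years):
        base = {(y, b): 0.0 for y in years for b in range(18)}
        base.update({(y, b): v for y, b, v in entries})
        return pd.DataFrame(
            [
                {"year": y, "sex": "female", "race_ethnicity": "Hispanic", "child_age": b, "cause": "other", "G_dedup": v}
                for (y, b), v in base.items()
            ]
        )

    def test_zero_grandparent_loss_reduces_to_orphanhood(self):
        years = list(range(1990, 2011))
        out = caregiver_prevalence(
            self._O_lifetime([2010]), self._G_dedup([], years), self._child_hazards(0.0, years), [2010]
        )
        assert np.allclose(out["L_lifetime"], out["O_lifetime"])

    def test_survival_product_starts_at_year_of_loss(self):
        # A single contribution of 100 at age 0 in the current year is
        # discounted by one factor (1 - h) — the j = 0 term — unlike the
        # orphanhood recursion which starts at j = 1.
        years = list(range(1990, 2011))
        out = caregiver_prevalence(
            self._O_lifetime([2010]).assign(lifetime=0.0),
            self._G_dedup([(2010, 0, 100.0)], years),
            self._child_hazards(0.01, years),
            [2010],
        )
        cell = out[(out.year == 2010) & (out.child_age == 0)]
        assert cell["L_lifetime"].iloc[0] == pytest.approx(99.0)

    def test_zero_child_hazard_gives_plain_cumulative_sum(self):
        years = list(range(1990, 2011))
        out = caregiver_prevalence(
            self._O_lifetime([2010]).assign(lifetime=0.0),
            self._G_dedup([(2008, 0, 10.0), (2009, 1, 20.0), (2010, 2, 30.0)], years),
            self._child_hazards(0.0, years),
            [2010],
        )
        cell = out[(out.year == 2010) & (out.child_age == 2)]
        assert cell["L_lifetime"].iloc[0] == pytest.approx(60.0)

    def test_history_shorter_than_child_age_rejected(self):
        years = list(range(2005, 2011))
        with pytest.raises(EstimationError):
            caregiver_prevalence(
                self._O_lifetime([2010]), self._G_dedup([], years), self._child_hazards(0.0, range(1990, 2011)), [2010]
            )
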