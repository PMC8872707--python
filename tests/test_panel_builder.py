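"""Rates, outcome transform, interpolation, lagging and sample filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from countydid.panel_builder import (
    FilterCriteria,
    apply_sample_filters,
    build_analysis_rows,
    compute_rate,
    interpolate_sparse_covariate,
    transform_outcome,
)
from countydid.synthetic_panel import AGES, COVARIATE_COLUMNS


def make_panel(
    n_counties=4,
    years=range(2008, 2013),
    funded_from=None,
    pop=100.0,
    births=2.0,
    distance_years=None,
):
    """Hand-built raw panel; funded_from maps county index -> first year."""
    funded_from = funded_from or {}
    recs = []
    for i in range(n_counties):
        for y in years:
            rec = {
                "county_id": f"C{i}",
                "state_id": f"S{i % 2}",
                "year": y,
            }
            for a in AGES:
                rec[f"births_age{a}"] = births
                rec[f"pop_age{a}"] = pop
            for c in COVARIATE_COLUMNS:
                rec[c] = 10.0
            if distance_years is not None and y not in distance_years:
                rec["abortion_distance"] = np.nan
            rec["funded"] = int(i in funded_from and y >= funded_from[i])
            recs.append(rec)
    return pd.DataFrame(recs)


class TestScalarOps:
    @pytest.mark.parametrize(
        "births,pop,expected", [(5, 1000, 5.0), (0, 250, 0.0), (3, 40, 75.0)]
    )
    def test_rate_per_thousand(self, births, pop, expected):
        assert compute_rate(births, pop) == expected

    def test_zero_population_is_domain_error(self):
        with pytest.raises(ValueError, match="population"):
            compute_rate(1, 0)

    @pytest.mark.parametrize("rate,expected", [(0.0, 0.0), (5.0, math.log(6.0))])
    def test_log1p_outcome(self, rate, expected):
        assert transform_outcome(rate) == pytest.approx(expected, abs=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            transform_outcome(-0.1)

    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    def test_transform_monotone_and_invertible(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert transform_outcome(lo) <= transform_outcome(hi)
        assert math.expm1(transform_outcome(r1)) == pytest.approx(r1, rel=1e-12, abs=1e-9)


class TestInterpolation:
    @pytest.mark.parametrize(
        "obs,year,expected",
        [
            ({2000: 10, 2011: 21}, 2005, 15.0),
            ({2000: 10, 2011: 21}, 1996, 6.0),
            ({2000: 10, 2011: 21, 2014: 30}, 2017, 39.0),
            ({2000: 10, 2011: 21, 2014: 30}, 2011, 21.0),
        ],
    )
    def test_interpolation_and_edge_slope_extrapolation(self, obs, year, expected):
        assert interpolate_sparse_covariate(obs, year) == pytest.approx(expected)

    def test_fewer_than_two_observations_rejected(self):
        with pytest.raises(ValueError):
            interpolate_sparse_covariate({2000: 10}, 2005)

    @given(
        st.floats(-100, 100),
        st.floats(-10, 10),
        st.integers(1990, 2020),
    )
    def test_collinear_knots_give_single_line(self, intercept, slope, year):
        """Three collinear knots behave identically to their two endpoints."""
        three = {2000: intercept, 2007: intercept + 7 * slope, 2014: intercept + 14 * slope}
        two = {2000: intercept, 2014: intercept + 14 * slope}
        assert interpolate_sparse_covariate(three, year) == pytest.approx(
            interpolate_sparse_covariate(two, year), rel=1e-9, abs=1e-7
        )


class TestSampleFilters:
    def make_10_county_fixture(self):
        panel = make_panel(n_counties=10, funded_from={5: 2010, 6: 2011})
        # C0: a zero-population year
        idx = (panel["county_id"] == "C0") & (panel["year"] == 2009)
        for a in AGES:
            panel.loc[idx, f"pop_age{a}"] = 0.0
        # C3: a missing covariate year
        panel.loc[
            (panel["county_id"] == "C3") & (panel["year"] == 2010), "unemployment"
        ] = np.nan
        # C6 first funded 2011: outside the allowed cohorts
        criteria = FilterCriteria.make(
            abstinence_counties=["C1", "C2"], allowed_cohort_years=[2010]
        )
        return panel, criteria

    def test_ordered_rule_counts_on_constructed_fixture(self):
        panel, criteria = self.make_10_county_fixture()
        kept, report = apply_sample_filters(panel, criteria)
        assert report.counts == (1, 2, 1, 1, 0)
        assert report.n_remaining == 5
        assert kept["county_id"].nunique() == 5

    def test_no_flags_keeps_everything(self):
        panel = make_panel(funded_from={1: 2010})
        kept, report = apply_sample_filters(panel)
        assert report.counts == (0, 0, 0, 0, 0)
        assert kept["county_id"].nunique() == panel["county_id"].nunique()

    def test_county_failing_two_rules_attributed_to_first(self):
        panel, _ = self.make_10_county_fixture()
        criteria = FilterCriteria.make(
            abstinence_counties=["C0", "C1", "C2"], allowed_cohort_years=[2010, 2011]
        )
        _, report = apply_sample_filters(panel, criteria)
        # C0 is both zero-population and abstinence-flagged: rule 1 claims it
        assert "C0" in report.excluded_ids[0]
        assert "C0" not in report.excluded_ids[1]
        assert report.counts[1] == 2

    def test_filters_idempotent(self):
        panel, criteria = self.make_10_county_fixture()
        once, r1 = apply_sample_filters(panel, criteria)
        twice, r2 = apply_sample_filters(once, criteria)
        pd.testing.assert_frame_equal(once, twice)
        assert r2.counts == (0, 0, 0, 0, 0)

    def test_excluded_state_rule(self):
        panel = make_panel()
        _, report = apply_sample_filters(
            panel, FilterCriteria.make(excluded_states=["S1"])
        )
        assert report.counts[-1] == 2

    def test_sparse_distance_filled_before_missing_rule(self):
        panel = make_panel(years=range(2008, 2016), distance_years={2009, 2012})
        kept, report = apply_sample_filters(panel)
        assert report.counts == (0, 0, 0, 0, 0)
        assert kept["abortion_distance"].notna().all()


class TestAnalysisRows:
    def test_one_year_treatment_lag(self):
        panel = make_panel(years=range(2008, 2013), funded_from={0: 2010})
        rows = build_analysis_rows(panel)
        c0 = rows[rows["county_id"] == "C0"].set_index("year")
        assert c0.loc[2010, "treat_lag"] == 0
        assert (c0.loc[2011:, "treat_lag"] == 1).all()
        assert (c0["group_year"] == 2011).all()

    def test_aggregate_rate_pools_births_over_pooled_population(self):
        panel = make_panel(n_counties=2, years=[2000, 2001])
        for a, b in zip(AGES, [1, 2, 3, 4, 5, 6]):
            panel[f"births_age{a}"] = b
        rows = build_analysis_rows(panel)
        # 21 births / 600 women -> 35 per 1,000
        assert rows["outcome"].iloc[0] == pytest.approx(np.log1p(35.0))

    def test_zero_lag_treats_funding_year_itself(self):
        panel = make_panel(years=range(2008, 2013), funded_from={0: 2010})
        rows = build_analysis_rows(panel, lag=0)
        c0 = rows[rows["county_id"] == "C0"].set_index("year")
        assert c0.loc[2010, "treat_lag"] == 1
        assert c0.loc[2009, "treat_lag"] == 0

    def test_first_year_dropped_when_lagged(self):
        panel = make_panel(years=range(2008, 2013))
        rows = build_analysis_rows(panel)
        assert rows["year"].min() == 2009

    def test_shifting_funding_shifts_first_treated_year(self):
        base = make_panel(years=range(2008, 2015), funded_from={0: 2010})
        shifted = make_panel(years=range(2008, 2015), funded_from={0: 2011})
        g_base = build_analysis_rows(base)["group_year"].max()
        g_shift = build_analysis_rows(shifted)["group_year"].max()
        assert g_shift == g_base + 1

    def test_age_specific_mode_stacks_ages(self):
        panel = make_panel(n_counties=2, years=[2000, 2001, 2002])
        rows = build_analysis_rows(panel, age_mode="age_specific")
        assert len(rows) == 2 * 2 * len(AGES)
        assert set(rows["age"]) == set(AGES)

    def test_unbalanced_panel_rejected_naming_county(self):
        panel = make_panel()
        panel = panel[~((panel["county_id"] == "C2") & (panel["year"] == 2010))]
        with pytest.raises(ValueError, match="C2"):
            build_analysis_rows(panel)
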