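"""Estimators, Wilson intervals, population summaries and masking."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.proportion import proportion_confint

from msprev import (
    average_point_prevalence,
    max_relative_difference,
    overlap_shares,
    period_prevalence,
    point_prevalence,
    summarize_counts,
    table3_summary,
    wilson_ci,
)
from msprev.prevalence import (
    PrevalenceEstimate,
    StratumScheme,
    estimates_frame,
    month_firsts,
)
from msprev.util import round_half_away

from .conftest import ident_series, make_cohort

D = dt.date


class TestWilson:
    def test_lower_bound_exactly_zero_at_k0(self):
        low, high = wilson_ci(0, 100)
        assert low == 0.0
        assert 0 < high < 0.05

    def test_upper_bound_exactly_one_at_kn(self):
        low, high = wilson_ci(100, 100)
        assert high == 1.0
        assert low > 0.95

    @pytest.mark.parametrize("k,n", [(5, 1000), (1, 7), (37, 120), (250, 100_000)])
    def test_matches_independent_implementation_to_10_digits(self, k, n):
        low, high = wilson_ci(k, n)
        ref_low, ref_high = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert low == pytest.approx(ref_low, rel=1e-10)
        assert high == pytest.approx(ref_high, rel=1e-10)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 3)

    @settings(derandomize=True, max_examples=100)
    @given(k=st.integers(0, 50), scale=st.integers(1, 4))
    def test_contains_point_estimate_and_narrows_with_n(self, k, scale):
        n = 50
        low, high = wilson_ci(k * scale, n * scale)
        assert low <= k / n <= high
        low2, high2 = wilson_ci(k * scale * 10, n * scale * 10)
        assert (high2 - low2) < (high - low) or k in (0,) and low == low2 == 0 and high2 < high


@pytest.fixture
def two_women_2010():
    cohort = make_cohort(
        [
            {"person_id": "a", "birth_date": "1980-01-01",
             "entry_date": "2010-01-01", "exit_date": "2010-12-31"},
            {"person_id": "b", "birth_date": "1982-01-01",
             "entry_date": "2010-01-01", "exit_date": "2010-12-31"},
        ]
    )
    ident = ident_series({"a": "2010-03-15"})
    return cohort, ident


class TestPointPrevalence:
    def test_monthly_points_flip_at_identification(self, two_women_2010):
        cohort, ident = two_women_2010
        values = [
            point_prevalence(cohort, ident, day)
            for day in month_firsts(D(2010, 1, 1), D(2010, 12, 31))
        ]
        assert values[:3] == [(0, 2)] * 3
        assert values[3:] == [(1, 2)] * 9

    def test_no_identifications_gives_zero_numerator(self, two_women_2010):
        cohort, _ = two_women_2010
        assert point_prevalence(cohort, ident_series({}), D(2010, 6, 1)) == (0, 2)

    def test_age_group_boundary_uses_completed_years(self):
        cohort = make_cohort(
            [{"person_id": "a", "birth_date": "1990-02-01",
              "entry_date": "2010-01-01", "exit_date": "2019-12-31"}]
        )
        day = D(2015, 1, 1)  # aged 24 years 11 months
        assert point_prevalence(cohort, ident_series({}), day, age_group=(15, 24))[1] == 1
        assert point_prevalence(cohort, ident_series({}), day, age_group=(25, 29))[1] == 0
        day = D(2015, 2, 1)  # 25th birthday
        assert point_prevalence(cohort, ident_series({}), day, age_group=(25, 29))[1] == 1


class TestAveragePointPrevalence:
    def test_two_women_fixture_is_37500_per_100k(self, two_women_2010):
        cohort, ident = two_women_2010
        est = average_point_prevalence(
            cohort, ident, (D(2010, 1, 1), D(2010, 12, 31)), algorithm_id="MS1"
        )
        assert est.prevalence_per_100k == pytest.approx(37_500.0)
        assert est.n_points == 12
        assert est.ci_low_per_100k <= est.prevalence_per_100k <= est.ci_high_per_100k

    def test_everyone_identified_saturates_at_100k(self, two_women_2010):
        cohort, _ = two_women_2010
        ident = ident_series({"a": "2009-01-01", "b": "2009-06-01"})
        est = average_point_prevalence(cohort, ident, (D(2010, 1, 1), D(2010, 12, 31)))
        assert est.prevalence_per_100k == pytest.approx(100_000.0)
        assert est.ci_high_per_100k == pytest.approx(100_000.0)

    def test_empty_denominator_returns_missing(self, two_women_2010):
        cohort, ident = two_women_2010
        assert average_point_prevalence(cohort, ident, (D(2012, 1, 1), D(2012, 12, 31))) is None

    def test_months_agree_with_point_prevalence_op(self, two_women_2010):
        cohort, ident = two_women_2010
        est = average_point_prevalence(cohort, ident, (D(2010, 1, 1), D(2010, 12, 31)))
        ratios = [
            k / n
            for k, n in (
                point_prevalence(cohort, ident, day)
                for day in month_firsts(D(2010, 1, 1), D(2010, 12, 31))
            )
        ]
        assert est.prevalence_per_100k == pytest.approx(np.mean(ratios) * 1e5)


def _windows(cohort):
    return cohort[["person_id", "entry_date", "exit_date"]].rename(
        columns={"entry_date": "start", "exit_date": "end"}
    )


class TestPeriodPrevalence:
    def test_five_women_two_identified(self):
        cohort = make_cohort(
            [
                {"person_id": p, "birth_date": "1980-01-01",
                 "entry_date": "2010-01-01", "exit_date": "2014-12-31"}
                for p in "abcde"
            ]
        )
        ident = ident_series({"a": "2011-01-01", "b": "2014-12-31"})  # b on the last day
        est = period_prevalence(
            cohort, _windows(cohort), ident, (D(2010, 1, 1), D(2014, 12, 31))
        )
        assert (est.numerator, est.denominator) == (2, 5)
        assert est.prevalence_per_100k == pytest.approx(40_000.0)

    def test_one_day_overlap_counts_in_denominator(self):
        cohort = make_cohort(
            [{"person_id": "a", "birth_date": "1980-01-01",
              "entry_date": "2009-06-01", "exit_date": "2010-01-01"}]
        )
        est = period_prevalence(
            cohort, _windows(cohort), ident_series({}), (D(2010, 1, 1), D(2014, 12, 31))
        )
        assert est.denominator == 1

    def test_identification_after_period_end_not_counted(self):
        cohort = make_cohort(
            [{"person_id": "a", "birth_date": "1980-01-01",
              "entry_date": "2010-01-01", "exit_date": "2014-12-31"}]
        )
        ident = ident_series({"a": "2015-01-01"})
        est = period_prevalence(
            cohort, _windows(cohort), ident, (D(2010, 1, 1), D(2014, 12, 31))
        )
        assert est.numerator == 0

    def test_age_stratum_requires_group_membership_during_period(self):
        cohort = make_cohort(
            [{"person_id": "a", "birth_date": "1990-06-15",
              "entry_date": "2010-01-01", "exit_date": "2019-12-31"}]
        )
        windows = _windows(cohort)
        period = (D(2010, 1, 1), D(2014, 12, 31))  # aged 19.5 to 24.5
        for group, expected in [((15, 24), 1), ((25, 29), 0), ((40, 49), 0)]:
            est = period_prevalence(cohort, windows, ident_series({}), period, age_group=group)
            n = 0 if est is None else est.denominator
            assert n == expected

    def test_period_at_least_point_on_first_day_for_closed_cohort(self, two_women_2010):
        cohort, ident = two_women_2010
        period = (D(2010, 1, 1), D(2010, 12, 31))
        k, n = point_prevalence(cohort, ident, period[0])
        est = period_prevalence(cohort, _windows(cohort), ident, period)
        assert est.prevalence_per_100k >= k / n * 1e5


class TestSummaries:
    def test_max_relative_difference_matches_published_examples(self):
        norway = {"MS1": 7351, "MS2": 7106, "MS3": 6586, "MS4": 7193, "MS5": 7057}
        haute_garonne = {"MS1": 105, "MS2": 75, "MS3": 57, "MS4": 67, "MS5": 19}
        assert round_half_away(max_relative_difference(norway), 1) == 10.4
        assert round_half_away(max_relative_difference(haute_garonne), 1) == 81.9

    def test_equal_counts_give_zero_spread(self):
        assert max_relative_difference({a: 7 for a in ("MS1", "MS2")}) == 0.0

    def test_all_zero_counts_are_undefined(self):
        assert max_relative_difference({"MS1": 0, "MS5": 0}) is None

    def test_percentages_of_study_population(self):
        df = summarize_counts({"MS1": 3985}, population=1_371_568)
        assert df.loc[0, "pct_rounded"] == 0.29

    def test_overlap_shares_from_identifications(self):
        ident = pd.DataFrame(
            {
                "person_id": ["a", "b", "c", "a", "b", "a"],
                "algorithm_id": ["MS1", "MS1", "MS1", "MS2", "MS2", "MS3"],
                "identification_date": pd.Timestamp("2010-01-01"),
            }
        )
        shares = overlap_shares(ident)
        assert shares.loc["MS1", "MS2"] == pytest.approx(100 * 2 / 3)
        assert shares.loc["MS2", "MS1"] == pytest.approx(100.0)
        assert shares.loc["MS3", "MS1"] == pytest.approx(100.0)

    def test_table3_summary_counts_unique_persons(self):
        cohort = make_cohort(
            [
                {"person_id": p, "birth_date": "1980-01-01",
                 "entry_date": "2010-01-01", "exit_date": "2014-12-31"}
                for p in "abcd"
            ]
        )
        ident = pd.DataFrame(
            {
                "person_id": ["a", "b", "a"],
                "algorithm_id": ["MS1", "MS1", "MS2"],
                "identification_date": pd.Timestamp("2011-01-01"),
            }
        )
        summary = table3_summary(cohort, ident)
        assert summary.counts == {"MS1": 2, "MS2": 1, "MS3": 0, "MS4": 0, "MS5": 0}
        assert summary.population == 4


class TestMasking:
    @pytest.mark.parametrize("numerator,masked", [(0, False), (1, True), (4, True), (5, False)])
    def test_mask_boundaries(self, numerator, masked):
        est = PrevalenceEstimate(
            period_label="2010-2014",
            age_label=None,
            algorithm_id="MS1",
            numerator=numerator,
            denominator=100,
            prevalence_per_100k=numerator / 100 * 1e5,
            ci_low_per_100k=0,
            ci_high_per_100k=1e5,
        )
        assert est.masked is masked
        frame = estimates_frame([est], masked_export=True)
        assert bool(frame.loc[0, "masked"]) is masked
        if masked:
            assert pd.isna(frame.loc[0, "prevalence_per_100k"])
            assert pd.isna(frame.loc[0, "numerator"])
        else:
            assert frame.loc[0, "prevalence_per_100k"] == est.prevalence_per_100k


class TestStratumScheme:
    def test_periods_clip_to_study_span(self):
        from msprev import get_preset

        scheme = StratumScheme()
        labels = [lab for _, _, lab in scheme.clipped_periods(get_preset("norway"))]
        assert labels == ["2008-2009", "2010-2014", "2015-2019"]
        labels = [lab for _, _, lab in scheme.clipped_periods(get_preset("valencian_region"))]
        assert labels == ["2013-2014", "2015-2019"]
        labels = [lab for _, _, lab in scheme.clipped_periods(get_preset("emilia_romagna"))]
        assert labels[0] == "2009"
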