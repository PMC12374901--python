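"""Follow-up construction: entry/exit rules, eligibility, pregnancy windows."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msprev import (
    CohortMember,
    Person,
    PregnancyEpisode,
    build_cohort,
    eligibility_childbearing,
    entry_exit_childbearing,
    pregnancy_windows,
)
from msprev.cohort import GLOBAL_END, GLOBAL_START
from msprev.util import add_years, add_years_series, merge_intervals

D = dt.date


class TestEntryExit:
    def test_entry_at_15th_birthday(self, long_profile):
        person = Person("w", D(1990, 6, 15), source_join_date=D(2000, 1, 1))
        assert entry_exit_childbearing(person, long_profile) == (D(2005, 6, 15), D(2019, 12, 31))

    def test_too_old_for_study_is_absent(self, long_profile):
        person = Person("w", D(1954, 1, 1), source_join_date=D(1954, 1, 1))
        assert entry_exit_childbearing(person, long_profile) is None

    def test_join_and_death_bound_follow_up(self, long_profile):
        person = Person(
            "w", D(1970, 3, 10), source_join_date=D(2007, 5, 1), death_date=D(2018, 2, 2)
        )
        assert entry_exit_childbearing(person, long_profile) == (D(2007, 5, 1), D(2018, 2, 2))

    def test_exit_is_day_before_50th_birthday(self, long_profile):
        person = Person("w", D(1960, 7, 1), source_join_date=D(1960, 7, 1))
        entry, exit_ = entry_exit_childbearing(person, long_profile)
        assert exit_ == D(2010, 6, 30)

    def test_source_study_period_clips_entry(self):
        from msprev import get_preset

        person = Person("w", D(1980, 1, 1), source_join_date=D(1980, 1, 1))
        entry, exit_ = entry_exit_childbearing(person, get_preset("norway"))
        assert (entry, exit_) == (D(2008, 1, 1), D(2019, 12, 31))


class TestEligibility:
    @pytest.mark.parametrize(
        "exit_date,expected",
        [(D(2010, 12, 31), True), (D(2010, 12, 30), False), (D(2019, 12, 31), True)],
    )
    def test_365_consecutive_days_boundary(self, exit_date, expected):
        member = CohortMember("w", D(2010, 1, 1), exit_date)
        assert eligibility_childbearing(member) is expected


class TestPregnancyWindows:
    def test_single_pregnancy_margins(self, pregnant_profile):
        person = Person("w", D(1985, 1, 1), source_join_date=D(1985, 1, 1))
        member = pregnancy_windows(
            person, [PregnancyEpisode("w", D(2015, 4, 1), D(2015, 12, 20))], pregnant_profile
        )
        assert member.entry_date == D(2015, 1, 1)
        assert member.exit_date == D(2016, 3, 19)
        assert member.coverage == 1.0

    def test_two_disjoint_pregnancies_coverage(self, pregnant_profile):
        person = Person("w", D(1985, 1, 1), source_join_date=D(1985, 1, 1))
        pregnancies = [
            PregnancyEpisode("w", D(2010, 4, 1), D(2010, 9, 28)),
            PregnancyEpisode("w", D(2013, 4, 1), D(2013, 9, 28)),
        ]
        member = pregnancy_windows(person, pregnancies, pregnant_profile)
        assert [w.days for w in member.windows] == [361, 361]
        assert member.entry_date == D(2010, 1, 1)
        assert member.exit_date == D(2013, 12, 27)
        assert member.follow_up_days == 1457
        assert member.coverage == pytest.approx(722 / 1457)

    def test_under_15_at_lmp_is_absent(self, pregnant_profile):
        person = Person("w", D(2000, 6, 1), source_join_date=D(2000, 6, 1))
        preg = PregnancyEpisode("w", D(2015, 3, 1), D(2015, 11, 20))  # aged 14 at LMP
        assert pregnancy_windows(person, [preg], pregnant_profile) is None

    def test_pregnancy_outside_study_period_dropped(self, pregnant_profile):
        person = Person("w", D(1985, 1, 1), source_join_date=D(1985, 1, 1))
        preg = PregnancyEpisode("w", D(2004, 6, 1), D(2005, 2, 20))  # straddles start
        assert pregnancy_windows(person, [preg], pregnant_profile) is None

    def test_overlapping_windows_merge(self, pregnant_profile):
        person = Person("w", D(1985, 1, 1), source_join_date=D(1985, 1, 1))
        pregnancies = [
            PregnancyEpisode("w", D(2010, 4, 1), D(2010, 9, 28)),
            PregnancyEpisode("w", D(2011, 1, 10), D(2011, 10, 1)),  # margins overlap
        ]
        member = pregnancy_windows(person, pregnancies, pregnant_profile)
        assert len(member.windows) == 1
        assert member.coverage == 1.0

    def test_out_of_order_pregnancies_are_sorted(self, pregnant_profile):
        person = Person("w", D(1985, 1, 1), source_join_date=D(1985, 1, 1))
        pregnancies = [
            PregnancyEpisode("w", D(2013, 4, 1), D(2013, 9, 28)),
            PregnancyEpisode("w", D(2010, 4, 1), D(2010, 9, 28)),
        ]
        member = pregnancy_windows(person, pregnancies, pregnant_profile)
        assert member.entry_date == D(2010, 1, 1)


@settings(derandomize=True, max_examples=150)
@given(
    birth=st.dates(min_value=D(1950, 1, 1), max_value=D(2010, 12, 31)),
    join_offset=st.integers(min_value=0, max_value=20000),
    span=st.integers(min_value=0, max_value=30000),
)
def test_follow_up_lies_within_study_and_age_bounds(birth, join_offset, span):
    from msprev import DataSourceProfile, PopulationType

    profile = DataSourceProfile(
        name="full",
        population_type=PopulationType.CHILDBEARING_AGE,
        study_start=D(2005, 1, 1),
        study_end=D(2019, 12, 31),
    )
    join = birth + dt.timedelta(days=join_offset)
    person = Person("w", birth, source_join_date=join, source_leave_date=join + dt.timedelta(span))
    result = entry_exit_childbearing(person, profile)
    if result is None:
        return
    entry, exit_ = result
    assert GLOBAL_START <= entry <= exit_ <= GLOBAL_END
    assert entry >= add_years(birth, 15)
    assert exit_ < add_years(birth, 50)


def test_vectorised_build_matches_scalar_rules(long_profile):
    persons = pd.DataFrame(
        {
            "person_id": ["a", "b", "c", "d"],
            "birth_date": pd.to_datetime(["1990-06-15", "1954-01-01", "1970-03-10", "1996-02-29"]),
            "death_date": pd.to_datetime([None, None, "2018-02-02", None]),
            "source_join_date": pd.to_datetime(
                ["2000-01-01", "1970-01-01", "2007-05-01", "1996-02-29"]
            ),
            "source_leave_date": pd.to_datetime([None, None, None, None]),
        }
    )
    cohort, windows = build_cohort(persons, None, long_profile)
    expected = {}
    for _, row in persons.iterrows():
        person = Person(
            row["person_id"],
            row["birth_date"].date(),
            source_join_date=row["source_join_date"].date(),
            death_date=None if pd.isna(row["death_date"]) else row["death_date"].date(),
        )
        result = entry_exit_childbearing(person, long_profile)
        if result and (result[1] - result[0]).days + 1 >= 365:
            expected[row["person_id"]] = result
    assert set(cohort["person_id"]) == set(expected)
    for _, row in cohort.iterrows():
        entry, exit_ = expected[row["person_id"]]
        assert row["entry_date"].date() == entry
        assert row["exit_date"].date() == exit_
    assert (cohort["coverage"] == 1.0).all()
    assert len(windows) == len(cohort)


def test_add_years_handles_leap_birthdays():
    assert add_years(D(1996, 2, 29), 15) == D(2011, 2, 28)
    series = pd.Series(pd.to_datetime(["1996-02-29", "1990-06-15"]))
    out = add_years_series(series, 15)
    assert out.tolist() == [pd.Timestamp("2011-02-28"), pd.Timestamp("2005-06-15")]


def test_merging_overlapping_windows_never_decreases_coverage():
    # the merged observed span is at least as long as any unmerged clipping
    intervals = [(D(2010, 1, 1), D(2010, 6, 30)), (D(2010, 5, 1), D(2010, 12, 31))]
    merged = merge_intervals(intervals)
    assert merged == [(D(2010, 1, 1), D(2010, 12, 31))]
    merged_days = sum((e - s).days + 1 for s, e in merged)
    assert merged_days >= max((e - s).days + 1 for s, e in intervals)
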