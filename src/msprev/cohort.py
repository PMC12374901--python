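"""Follow-up construction and eligibility.

Two source regimes exist.  Sources covering all women of childbearing age
give each woman a single follow-up span from cohort entry (latest of joining
the source, 15th birthday, source study start, and the overall study start)
to cohort exit (earliest of leaving the source, death, the day before the
50th birthday, and the study end); eligibility requires at least 365
consecutive days of complete coverage.  Pregnant-only sources observe a woman
only around her pregnancies: each complete in-study pregnancy (while she is
aged 15-49 throughout) opens a window from a fixed margin before the last
menstrual period to a fixed margin after the pregnancy end; overlapping
windows merge, and coverage is the observed share of the entry-to-exit span.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .profiles import DataSourceProfile, PopulationType
from .records import CohortMember, ObservationWindow, Person, PregnancyEpisode
from .util import add_years, add_years_series, day_count, merge_intervals

#: Overall study bounds shared by every source.
GLOBAL_START = dt.date(2005, 1, 1)
GLOBAL_END = dt.date(2019, 12, 31)

MIN_AGE = 15
MAX_AGE = 50  # exit the day before the 50th birthday

MIN_FOLLOW_UP_DAYS = 365

COHORT_COLUMNS = [
    "person_id",
    "birth_date",
    "entry_date",
    "exit_date",
    "n_windows",
    "follow_up_days",
    "observed_days",
    "coverage",
]


def entry_exit_childbearing(
    person: Person, profile: DataSourceProfile
) -> tuple[dt.date, dt.date] | None:
    """Entry/exit dates for a childbearing-age source; None when never in study."""
    entry = max(
        person.source_join_date,
        add_years(person.birth_date, MIN_AGE),
        profile.study_start,
        GLOBAL_START,
    )
    study_end = min(profile.study_end, GLOBAL_END)
    exit_ = min(
        person.source_leave_date or study_end,
        person.death_date or study_end,
        add_years(person.birth_date, MAX_AGE) - dt.timedelta(days=1),
        study_end,
    )
    if entry > exit_:
        return None
    return entry, exit_


def eligibility_childbearing(member: CohortMember) -> bool:
    """At least 365 consecutive fully covered days."""
    return member.follow_up_days >= MIN_FOLLOW_UP_DAYS


def pregnancy_windows(
    person: Person,
    pregnancies: list[PregnancyEpisode],
    profile: DataSourceProfile,
) -> CohortMember | None:
    """Pregnancy-anchored follow-up for a pregnant-only source.

    Keeps complete in-study pregnancies during which the woman is aged 15-49
    throughout, opens a margin-extended window per pregnancy, merges overlaps.
    Returns None when no pregnancy qualifies.
    """
    if profile.population_type is not PopulationType.PREGNANT_ONLY:
        raise ValueError("pregnancy_windows requires a pregnant_only profile")
    bday15 = add_years(person.birth_date, MIN_AGE)
    bday50 = add_years(person.birth_date, MAX_AGE)
    kept = [
        p
        for p in sorted(pregnancies, key=lambda p: p.lmp_date)
        if p.lmp_date >= profile.study_start
        and p.end_date <= profile.study_end
        and p.lmp_date >= bday15
        and p.end_date < bday50
    ]
    if not kept:
        return None
    raw = [
        (
            p.lmp_date - dt.timedelta(days=profile.pre_lmp_margin_days),
            p.end_date + dt.timedelta(days=profile.post_pregnancy_margin_days),
        )
        for p in kept
    ]
    windows = [ObservationWindow(s, e) for s, e in merge_intervals(raw)]
    return CohortMember(
        person_id=person.person_id,
        entry_date=windows[0].start,
        exit_date=windows[-1].end,
        windows=windows,
    )


def coverage(member: CohortMember) -> float:
    """Observed share of the follow-up span, in (0, 1]."""
    return member.coverage


# ---------------------------------------------------------------------------
# Bulk (DataFrame) construction


def _build_childbearing(persons: pd.DataFrame, profile: DataSourceProfile) -> pd.DataFrame:
    study_start = pd.Timestamp(max(profile.study_start, GLOBAL_START))
    study_end = pd.Timestamp(min(profile.study_end, GLOBAL_END))
    bday15 = add_years_series(persons["birth_date"], MIN_AGE)
    exit_age = add_years_series(persons["birth_date"], MAX_AGE) - pd.Timedelta(days=1)
    entry = persons["source_join_date"].clip(lower=study_start)
    entry = np.maximum(entry, bday15).clip(lower=study_start)
    exit_ = persons["source_leave_date"].fillna(study_end)
    exit_ = np.minimum(exit_, persons["death_date"].fillna(study_end))
    exit_ = np.minimum(exit_, exit_age).clip(upper=study_end)
    out = pd.DataFrame(
        {
            "person_id": persons["person_id"],
            "birth_date": persons["birth_date"],
            "entry_date": entry,
            "exit_date": exit_,
        }
    )
    out = out[out["entry_date"] <= out["exit_date"]].copy()
    out["n_windows"] = 1
    out["follow_up_days"] = (out["exit_date"] - out["entry_date"]).dt.days + 1
    out = out[out["follow_up_days"] >= MIN_FOLLOW_UP_DAYS].reset_index(drop=True)
    out["observed_days"] = out["follow_up_days"]
    out["coverage"] = 1.0
    return out


def _build_pregnant_only(
    persons: pd.DataFrame, pregnancies: pd.DataFrame, profile: DataSourceProfile
) -> tuple[pd.DataFrame, pd.DataFrame]:
    birth_by_id = dict(zip(persons["person_id"], persons["birth_date"]))
    members: list[dict] = []
    window_rows: list[dict] = []
    for pid, group in pregnancies.groupby("person_id", sort=True):
        birth = birth_by_id.get(pid)
        if birth is None:
            continue
        person = Person(person_id=pid, birth_date=birth.date(), source_join_date=birth.date())
        episodes = [
            PregnancyEpisode(pid, lmp.date(), end.date())
            for lmp, end in zip(group["lmp_date"], group["end_date"])
        ]
        member = pregnancy_windows(person, episodes, profile)
        if member is None:
            continue
        members.append(
            {
                "person_id": pid,
                "birth_date": birth,
                "entry_date": pd.Timestamp(member.entry_date),
                "exit_date": pd.Timestamp(member.exit_date),
                "n_windows": len(member.windows),
                "follow_up_days": member.follow_up_days,
                "observed_days": member.observed_days,
                "coverage": member.coverage,
            }
        )
        window_rows.extend(
            {"person_id": pid, "start": pd.Timestamp(w.start), "end": pd.Timestamp(w.end)}
            for w in member.windows
        )
    cohort = pd.DataFrame(members, columns=COHORT_COLUMNS)
    windows = pd.DataFrame(window_rows, columns=["person_id", "start", "end"])
    return cohort, windows


def build_cohort(
    persons: pd.DataFrame,
    pregnancies: pd.DataFrame | None,
    profile: DataSourceProfile,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct the eligible cohort and its observation windows.

    Returns ``(cohort, windows)``: one row per eligible woman with entry/exit
    dates, follow-up length and coverage; and one row per observation window.
    For childbearing-age sources each woman has a single window spanning her
    whole follow-up and coverage 1.
    """
    if profile.population_type is PopulationType.CHILDBEARING_AGE:
        cohort = _build_childbearing(persons, profile)
        windows = cohort[["person_id", "entry_date", "exit_date"]].rename(
            columns={"entry_date": "start", "exit_date": "end"}
        )
        return cohort, windows
    if pregnancies is None or pregnancies.empty:
        empty = pd.DataFrame(columns=COHORT_COLUMNS)
        return empty, pd.DataFrame(columns=["person_id", "start", "end"])
    return _build_pregnant_only(persons, pregnancies, profile)
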