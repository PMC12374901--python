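"""The five rule-based MS case-identification algorithms.

Each algorithm classifies a woman as an MS case as soon as her stream of
qualifying events — MS diagnoses recorded in inpatient, outpatient/other or
primary care, and dispensings/prescriptions of disease-modifying therapies
(DMTs), MS-specific or not — contains a *satisfying selection* of distinct
events:

* **MS1** — one MS diagnosis (any setting) or one MS-specific DMT.
* **MS2** — MS1 plus one further event among diagnoses and any DMT
  (two distinct events in total).
* **MS3** — MS2 plus one further such event (three distinct events).
* **MS4** — one inpatient diagnosis, or two diagnoses from
  outpatient/other or primary care.
* **MS5** — two MS diagnoses, any setting.

Whenever a selection uses two or more diagnoses, those diagnoses must be
pairwise at least 30 days apart.  The identification date is the date the
criteria are first met: the latest event date within the earliest-finishing
satisfying selection (for MS5, the date of the second diagnosis).  Status is
absorbing — once identified, a woman counts as an MS case until the end of
her follow-up.

Distinct events: two records on the same date with different categories are
two events; same-date records of the same category collapse to one (treated
as administrative repeats).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .profiles import DataSourceProfile
from .records import DIAGNOSIS_TYPES, EventType, ObservationWindow, QualifyingEvent

ALGORITHM_IDS = ("MS1", "MS2", "MS3", "MS4", "MS5")

#: minimum separation, in days, between any two diagnoses of one selection
DIAGNOSIS_SEPARATION_DAYS = 30


@dataclass(frozen=True)
class MSIdentification:
    person_id: str
    algorithm_id: str
    identification_date: dt.date | None


def _distinct_events(
    events: Iterable[QualifyingEvent | tuple[dt.date, EventType]],
    window: ObservationWindow | None,
) -> dict[EventType, list[dt.date]]:
    """Deduplicate to (date, type) pairs within ``window``, dates sorted per type."""
    seen: set[tuple[dt.date, EventType]] = set()
    for ev in events:
        if isinstance(ev, QualifyingEvent):
            date, etype = ev.event_date, ev.event_type
        else:
            date, etype = ev[0], EventType(ev[1])
        if window is not None and not window.contains(date):
            continue
        seen.add((date, etype))
    by_type: dict[EventType, list[dt.date]] = {t: [] for t in EventType}
    for date, etype in sorted(seen):
        by_type[etype].append(date)
    return by_type


def _max_separated(dates: Sequence[dt.date], separation_days: int) -> int:
    """Largest number of dates selectable pairwise >= separation_days apart.

    Greedy earliest-first selection on sorted dates is optimal for this
    interval-scheduling structure.
    """
    count = 0
    last: dt.date | None = None
    for d in dates:  # sorted, possibly with duplicates
        if last is None or (d - last).days >= separation_days:
            count += 1
            last = d
    return count


def _merge_sorted(*lists: Sequence[dt.date]) -> list[dt.date]:
    return sorted(d for lst in lists for d in lst)


def _satisfied(
    by_type: dict[EventType, list[dt.date]],
    algorithm_id: str,
    separation_days: int,
    ms4_separation: bool,
) -> bool:
    """Does some selection of the given distinct events satisfy the algorithm?

    The search is over counts: a selection with ``d`` diagnoses and ``m`` DMT
    events exists iff ``d`` diagnoses can be chosen pairwise separated (greedy
    maximum) and ``m`` distinct DMT events exist, with at least one event from
    the first-slot set (diagnoses or MS-specific DMT).
    """
    diag = _merge_sorted(*(by_type[t] for t in DIAGNOSIS_TYPES))
    n_spec = len(by_type[EventType.DMT_SPECIFIC])
    n_dmt = n_spec + len(by_type[EventType.DMT_NONSPECIFIC])
    if algorithm_id == "MS1":
        return bool(diag) or n_spec >= 1
    if algorithm_id == "MS2":
        return (
            (len(diag) >= 1 and n_dmt >= 1)  # one diagnosis + one DMT
            or (n_spec >= 1 and n_dmt >= 2)  # MS-specific DMT + another DMT
            or _max_separated(diag, separation_days) >= 2  # two separated diagnoses
        )
    if algorithm_id == "MS3":
        sep = _max_separated(diag, separation_days)
        return (
            sep >= 3
            or (sep >= 2 and n_dmt >= 1)
            or (len(diag) >= 1 and n_dmt >= 2)
            or (n_spec >= 1 and n_dmt >= 3)
        )
    if algorithm_id == "MS4":
        if by_type[EventType.DX_INPATIENT]:
            return True
        non_inpatient = _merge_sorted(
            by_type[EventType.DX_OUTPATIENT_OTHER], by_type[EventType.DX_PRIMARY_CARE]
        )
        if ms4_separation:
            return _max_separated(non_inpatient, separation_days) >= 2
        return len(non_inpatient) >= 2
    if algorithm_id == "MS5":
        return _max_separated(diag, separation_days) >= 2
    raise ValueError(f"unknown algorithm_id {algorithm_id!r}")


def evaluate(
    algorithm_id: str,
    events: Iterable[QualifyingEvent | tuple[dt.date, EventType]],
    event_window: ObservationWindow | None = None,
    separation_days: int = DIAGNOSIS_SEPARATION_DAYS,
    ms4_separation: bool = True,
) -> dt.date | None:
    """Earliest date on which the algorithm's criteria are met, else None.

    Only events inside ``event_window`` (the source's usable span, including
    any historical lookback) are considered.  Because satisfying a criterion
    is monotone in the event set, the identification date is the first event
    date whose prefix of events is satisfiable.

    ``ms4_separation`` toggles whether MS4's two-diagnosis branch enforces the
    30-day separation (on by default; off for sensitivity analyses).
    """
    if algorithm_id not in ALGORITHM_IDS:
        raise ValueError(f"unknown algorithm_id {algorithm_id!r}")
    by_type = _distinct_events(events, event_window)
    all_dates = sorted({d for dates in by_type.values() for d in dates})
    prefix: dict[EventType, list[dt.date]] = {t: [] for t in EventType}
    cursor = {t: 0 for t in EventType}
    for t_date in all_dates:
        for etype in EventType:
            dates = by_type[etype]
            i = cursor[etype]
            while i < len(dates) and dates[i] <= t_date:
                prefix[etype].append(dates[i])
                i += 1
            cursor[etype] = i
        if _satisfied(prefix, algorithm_id, separation_days, ms4_separation):
            return t_date
    return None


def identify_all(
    events: Iterable[QualifyingEvent | tuple[dt.date, EventType]],
    event_window: ObservationWindow | None = None,
    person_id: str = "",
    separation_days: int = DIAGNOSIS_SEPARATION_DAYS,
    ms4_separation: bool = True,
) -> dict[str, MSIdentification]:
    """Apply all five algorithms to one woman's event stream."""
    events = list(events)
    return {
        alg: MSIdentification(
            person_id=person_id,
            algorithm_id=alg,
            identification_date=evaluate(
                alg, events, event_window, separation_days, ms4_separation
            ),
        )
        for alg in ALGORITHM_IDS
    }


def identify_cohort(
    events: pd.DataFrame,
    profile: DataSourceProfile,
    separation_days: int = DIAGNOSIS_SEPARATION_DAYS,
    ms4_separation: bool = True,
) -> pd.DataFrame:
    """Identification dates for every person with events, all five algorithms.

    ``events`` is the bulk table (person_id, event_date, event_type).  The
    usable window is the profile's identification span: from its historical
    start (when lookback exists) or study start, through study end.  Returns a
    long table (person_id, algorithm_id, identification_date) with one row per
    identified (person, algorithm) pair.
    """
    window = ObservationWindow(profile.identification_start, profile.study_end)
    rows: list[dict] = []
    for pid, group in events.groupby("person_id", sort=True):
        stream = [
            (date.date(), EventType(etype))
            for date, etype in zip(group["event_date"], group["event_type"])
        ]
        for alg, ident in identify_all(
            stream, window, pid, separation_days, ms4_separation
        ).items():
            if ident.identification_date is not None:
                rows.append(
                    {
                        "person_id": pid,
                        "algorithm_id": alg,
                        "identification_date": pd.Timestamp(ident.identification_date),
                    }
                )
    return pd.DataFrame(rows, columns=["person_id", "algorithm_id", "identification_date"])
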