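"""Record types of the simplified observational-health data model.

Four event-level tables describe a data source: persons, MS-qualifying events
(diagnoses by care setting, disease-modifying-therapy dispensings/prescriptions),
pregnancy episodes, and the source profile.  These dataclasses are the scalar
view of one row; bulk data travels as pandas DataFrames with the same columns
(see :mod:`msprev.io` for the column dictionary).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum

from .util import day_count

# A pregnancy from last menstrual period to end should not plausibly exceed this.
MAX_PREGNANCY_DAYS = 320


class EventType(str, Enum):
    """The five categories of MS-qualifying events.

    Diagnoses are split by care setting; disease-modifying therapies (DMTs)
    are split into MS-specific (MS is the only indication) and non-specific
    (indications besides MS exist).
    """

    DX_INPATIENT = "dx_inpatient"
    DX_OUTPATIENT_OTHER = "dx_outpatient_other"
    DX_PRIMARY_CARE = "dx_primary_care"
    DMT_SPECIFIC = "dmt_specific"
    DMT_NONSPECIFIC = "dmt_nonspecific"


DIAGNOSIS_TYPES = frozenset(
    {EventType.DX_INPATIENT, EventType.DX_OUTPATIENT_OTHER, EventType.DX_PRIMARY_CARE}
)
DMT_TYPES = frozenset({EventType.DMT_SPECIFIC, EventType.DMT_NONSPECIFIC})


@dataclass(frozen=True)
class Person:
    person_id: str
    birth_date: dt.date
    source_join_date: dt.date
    death_date: dt.date | None = None
    source_leave_date: dt.date | None = None

    def __post_init__(self) -> None:
        if self.death_date is not None and not self.birth_date < self.death_date:
            raise ValueError(f"person {self.person_id}: birth_date must precede death_date")
        if (
            self.source_leave_date is not None
            and not self.source_join_date <= self.source_leave_date
        ):
            raise ValueError(
                f"person {self.person_id}: source_join_date must not follow source_leave_date"
            )


@dataclass(frozen=True)
class QualifyingEvent:
    person_id: str
    event_date: dt.date
    event_type: EventType

    def __post_init__(self) -> None:
        object.__setattr__(self, "event_type", EventType(self.event_type))


@dataclass(frozen=True)
class PregnancyEpisode:
    person_id: str
    lmp_date: dt.date  # first day of last menstrual period
    end_date: dt.date

    def __post_init__(self) -> None:
        if not self.lmp_date < self.end_date:
            raise ValueError(f"person {self.person_id}: lmp_date must precede end_date")
        if (self.end_date - self.lmp_date).days > MAX_PREGNANCY_DAYS:
            raise ValueError(
                f"person {self.person_id}: pregnancy longer than {MAX_PREGNANCY_DAYS} days"
            )


@dataclass(frozen=True)
class ObservationWindow:
    """A closed [start, end] interval during which a woman is observable."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if not self.start <= self.end:
            raise ValueError("window start must not follow end")

    @property
    def days(self) -> int:
        return day_count(self.start, self.end)

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.end


@dataclass
class CohortMember:
    """A woman's follow-up: entry/exit span, observation windows and coverage.

    For childbearing-age sources the single window spans entry to exit and
    coverage is 1.  For pregnant-only sources windows are pregnancy-anchored
    and coverage is the observed share of the follow-up span.
    """

    person_id: str
    entry_date: dt.date
    exit_date: dt.date
    windows: list[ObservationWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entry_date <= self.exit_date:
            raise ValueError(f"member {self.person_id}: entry after exit")
        if not self.windows:
            self.windows = [ObservationWindow(self.entry_date, self.exit_date)]
        for w, nxt in zip(self.windows, self.windows[1:]):
            if nxt.start <= w.end:
                raise ValueError(f"member {self.person_id}: windows overlap or are unsorted")
        if self.windows[0].start != self.entry_date or self.windows[-1].end != self.exit_date:
            raise ValueError(f"member {self.person_id}: windows must span entry to exit")

    @property
    def follow_up_days(self) -> int:
        return day_count(self.entry_date, self.exit_date)

    @property
    def observed_days(self) -> int:
        return sum(w.days for w in self.windows)

    @property
    def coverage(self) -> float:
        return self.observed_days / self.follow_up_days
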