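"""Data-source profiles: what a source observes, and when.

A :class:`DataSourceProfile` declares everything source-specific the analysis
needs: whether the source covers all women of childbearing age or only
pregnant women, the study period actually covered, an optional historical
lookback usable for case identification only, which of the five event
categories the source records, and — for pregnant-only sources — the margins
around each pregnancy during which data are collected.

Six presets mirror the component-availability matrix of the European sources
the design targets (two national registries with full availability, two
regional inpatient+medication sources, one inpatient+primary-care source with
historical lookback, and a pregnancy-window-limited cohort).
"""

from __future__ import annotations

import datetime as dt
import json
from enum import Enum
from pathlib import Path

from pydantic import BaseModel, model_validator

from .records import EventType


class PopulationType(str, Enum):
    CHILDBEARING_AGE = "childbearing_age"
    PREGNANT_ONLY = "pregnant_only"


class DataSourceProfile(BaseModel):
    name: str
    population_type: PopulationType
    study_start: dt.date
    study_end: dt.date
    #: events from here (before study_start) usable for identification only
    historical_start: dt.date | None = None
    has_inpatient_dx: bool = True
    has_outpatient_other_dx: bool = True
    has_primary_care_dx: bool = True
    has_medication: bool = True
    #: data collection starts this many days before each pregnancy's LMP
    pre_lmp_margin_days: int = 0
    #: ... and ends this many days after each pregnancy's end
    post_pregnancy_margin_days: int = 0

    @model_validator(mode="after")
    def _check(self) -> "DataSourceProfile":
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")
        if self.historical_start is not None and self.historical_start > self.study_start:
            raise ValueError("historical_start must not follow study_start")
        if not any(
            [
                self.has_inpatient_dx,
                self.has_outpatient_other_dx,
                self.has_primary_care_dx,
                self.has_medication,
            ]
        ):
            raise ValueError("at least one event-type availability flag must be set")
        if self.pre_lmp_margin_days < 0 or self.post_pregnancy_margin_days < 0:
            raise ValueError("pregnancy margins must be non-negative")
        return self

    @property
    def identification_start(self) -> dt.date:
        """Earliest date of events usable for case identification."""
        return self.historical_start or self.study_start

    def available_event_types(self) -> frozenset[EventType]:
        types: set[EventType] = set()
        if self.has_inpatient_dx:
            types.add(EventType.DX_INPATIENT)
        if self.has_outpatient_other_dx:
            types.add(EventType.DX_OUTPATIENT_OTHER)
        if self.has_primary_care_dx:
            types.add(EventType.DX_PRIMARY_CARE)
        if self.has_medication:
            types.update({EventType.DMT_SPECIFIC, EventType.DMT_NONSPECIFIC})
        return frozenset(types)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DataSourceProfile":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _d(iso: str) -> dt.date:
    return dt.date.fromisoformat(iso)


#: Source-shaped presets.  Availability flags and population types follow the
#: published component matrix of the six European sources; study spans follow
#: the periods those sources actually covered.  Margins: "3 months" = 90 days,
#: "2.5 months" = 76 days, as fixed day counts.
PRESETS: dict[str, DataSourceProfile] = {
    "norway": DataSourceProfile(
        name="norway",
        population_type=PopulationType.CHILDBEARING_AGE,
        study_start=_d("2008-01-01"),
        study_end=_d("2019-12-31"),
    ),
    "emilia_romagna": DataSourceProfile(
        name="emilia_romagna",
        population_type=PopulationType.CHILDBEARING_AGE,
        study_start=_d("2009-01-01"),
        study_end=_d("2019-12-31"),
        has_primary_care_dx=False,
    ),
    "wales": DataSourceProfile(
        name="wales",
        population_type=PopulationType.CHILDBEARING_AGE,
        study_start=_d("2005-01-01"),
        study_end=_d("2019-12-31"),
        historical_start=_d("1998-01-01"),
        has_outpatient_other_dx=False,
    ),
    "finland": DataSourceProfile(
        name="finland",
        population_type=PopulationType.PREGNANT_ONLY,
        study_start=_d("2005-01-01"),
        study_end=_d("2018-12-31"),
        pre_lmp_margin_days=90,
        post_pregnancy_margin_days=90,
    ),
    "valencian_region": DataSourceProfile(
        name="valencian_region",
        population_type=PopulationType.PREGNANT_ONLY,
        study_start=_d("2013-01-01"),
        study_end=_d("2019-12-31"),
        has_outpatient_other_dx=False,
        has_primary_care_dx=False,
        pre_lmp_margin_days=90,
        post_pregnancy_margin_days=90,
    ),
    "haute_garonne": DataSourceProfile(
        name="haute_garonne",
        population_type=PopulationType.PREGNANT_ONLY,
        study_start=_d("2005-01-01"),
        study_end=_d("2019-12-31"),
        has_outpatient_other_dx=False,
        has_primary_care_dx=False,
        pre_lmp_margin_days=76,
        post_pregnancy_margin_days=0,
    ),
}


def get_preset(name: str) -> DataSourceProfile:
    try:
        return PRESETS[name].model_copy(deep=True)
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
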