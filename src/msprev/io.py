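"""Delimited-file readers and writers for the four model tables.

Column dictionary (comma-delimited, UTF-8, header row required, ISO-8601 dates,
optional dates serialised as the empty string):

* ``persons.csv`` — person_id, birth_date, death_date, source_join_date,
  source_leave_date
* ``events.csv`` — person_id, event_date, event_type
* ``pregnancies.csv`` — person_id, lmp_date, end_date
* ``profile.json`` — :class:`~msprev.profiles.DataSourceProfile` fields

Readers validate invariants up front (parseable dates, known event types,
unique person ids) and, in strict mode, reject events whose category the
source profile declares unavailable; in lax mode those events are dropped
with a single logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .profiles import DataSourceProfile
from .records import MAX_PREGNANCY_DAYS, EventType

logger = logging.getLogger(__name__)

PERSON_COLUMNS = ["person_id", "birth_date", "death_date", "source_join_date", "source_leave_date"]
EVENT_COLUMNS = ["person_id", "event_date", "event_type"]
PREGNANCY_COLUMNS = ["person_id", "lmp_date", "end_date"]

_DATE_COLUMNS = {
    "persons": ["birth_date", "death_date", "source_join_date", "source_leave_date"],
    "events": ["event_date"],
    "pregnancies": ["lmp_date", "end_date"],
}
_OPTIONAL_DATES = {"death_date", "source_leave_date"}


class TableValidationError(ValueError):
    """A table violated the column dictionary or a record invariant."""


def _parse_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for col in _DATE_COLUMNS[table]:
        raw = df[col].astype("string").str.strip()
        if col in _OPTIONAL_DATES:
            raw = raw.replace("", pd.NA)
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, counting the header line
            raise TableValidationError(
                f"{table}: malformed date {raw[bad.idxmax()]!r} in column {col!r}, file row {row}"
            )
        if col not in _OPTIONAL_DATES and parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise TableValidationError(f"{table}: missing required date {col!r}, file row {row}")
        df[col] = parsed
    return df


def _require_columns(df: pd.DataFrame, columns: list[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableValidationError(f"{table}: missing columns {missing}")


def read_persons(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str}, keep_default_na=False)
    _require_columns(df, PERSON_COLUMNS, "persons")
    df = _parse_dates(df[PERSON_COLUMNS].copy(), "persons")
    dup = df["person_id"].duplicated()
    if dup.any():
        raise TableValidationError(
            f"persons: duplicate person_id {df.loc[dup.idxmax(), 'person_id']!r}"
        )
    bad = df["death_date"].notna() & (df["birth_date"] >= df["death_date"])
    if bad.any():
        raise TableValidationError("persons: birth_date on or after death_date")
    bad = df["source_leave_date"].notna() & (df["source_join_date"] > df["source_leave_date"])
    if bad.any():
        raise TableValidationError("persons: source_join_date after source_leave_date")
    return df


def read_events(
    path: str | Path, profile: DataSourceProfile | None = None, strict: bool = True
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "event_type": str}, keep_default_na=False)
    _require_columns(df, EVENT_COLUMNS, "events")
    df = _parse_dates(df[EVENT_COLUMNS].copy(), "events")
    known = {e.value for e in EventType}
    unknown = ~df["event_type"].isin(known)
    if unknown.any():
        row = int(unknown.idxmax()) + 2
        raise TableValidationError(
            f"events: unknown event_type {df.loc[unknown.idxmax(), 'event_type']!r}, file row {row}"
        )
    if profile is not None:
        allowed = {e.value for e in profile.available_event_types()}
        bad = ~df["event_type"].isin(allowed)
        if bad.any():
            if strict:
                row = int(bad.idxmax()) + 2
                raise TableValidationError(
                    f"events: event_type {df.loc[bad.idxmax(), 'event_type']!r} not available "
                    f"in source {profile.name!r}, file row {row}"
                )
            logger.warning(
                "events: dropped %d events with types unavailable in source %s",
                int(bad.sum()),
                profile.name,
            )
            df = df[~bad].reset_index(drop=True)
    return df


def read_pregnancies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str}, keep_default_na=False)
    _require_columns(df, PREGNANCY_COLUMNS, "pregnancies")
    df = _parse_dates(df[PREGNANCY_COLUMNS].copy(), "pregnancies")
    if (df["lmp_date"] >= df["end_date"]).any():
        raise TableValidationError("pregnancies: lmp_date on or after end_date")
    if ((df["end_date"] - df["lmp_date"]).dt.days > MAX_PREGNANCY_DAYS).any():
        raise TableValidationError(f"pregnancies: duration exceeds {MAX_PREGNANCY_DAYS} days")
    return df


def read_tables(
    directory: str | Path, profile: DataSourceProfile | None = None, strict: bool = True
) -> dict[str, pd.DataFrame]:
    """Read persons/events/pregnancies tables from ``directory``.

    A missing ``pregnancies.csv`` yields an empty table (childbearing-age
    sources have no pregnancy input).
    """
    directory = Path(directory)
    tables = {
        "persons": read_persons(directory / "persons.csv"),
        "events": read_events(directory / "events.csv", profile=profile, strict=strict),
    }
    preg_path = directory / "pregnancies.csv"
    if preg_path.exists():
        tables["pregnancies"] = read_pregnancies(preg_path)
    else:
        tables["pregnancies"] = pd.DataFrame(
            {c: pd.Series(dtype="datetime64[ns]" if c != "person_id" else str)
             for c in PREGNANCY_COLUMNS}
        )
    return tables


def _validate_for_write(tables: Mapping[str, pd.DataFrame]) -> None:
    persons = tables["persons"]
    if persons["person_id"].duplicated().any():
        raise TableValidationError("refusing to write persons with duplicate person_id")
    bad = persons["death_date"].notna() & (persons["birth_date"] >= persons["death_date"])
    if bad.any():
        raise TableValidationError("refusing to write persons with birth_date >= death_date")
    events = tables["events"]
    known = {e.value for e in EventType}
    if (~events["event_type"].isin(known)).any():
        raise TableValidationError("refusing to write events with unknown event_type")
    preg = tables.get("pregnancies")
    if preg is not None and len(preg) and (preg["lmp_date"] >= preg["end_date"]).any():
        raise TableValidationError("refusing to write pregnancies with lmp_date >= end_date")


def write_tables(
    tables: Mapping[str, pd.DataFrame],
    directory: str | Path,
    profile: DataSourceProfile | None = None,
) -> dict[str, Path]:
    """Write the model tables as CSV (plus ``profile.json`` when given).

    Records are validated first; an invariant violation refuses the whole
    write.  Dates serialise as ISO-8601; absent optional dates as empty
    fields, which :func:`read_tables` restores as missing.
    """
    _validate_for_write(tables)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    columns = {"persons": PERSON_COLUMNS, "events": EVENT_COLUMNS, "pregnancies": PREGNANCY_COLUMNS}
    paths: dict[str, Path] = {}
    for name, cols in columns.items():
        if name not in tables:
            continue
        df = tables[name].copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
            df[col] = df[col].fillna("")
        path = directory / f"{name}.csv"
        df[cols].to_csv(path, index=False)
        paths[name] = path
    if profile is not None:
        paths["profile"] = directory / "profile.json"
        profile.to_json(paths["profile"])
    return paths
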