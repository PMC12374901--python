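"""Brute-force subset-enumeration oracle for the five identification rules.

Independent of the library's prefix-satisfiability implementation: it
enumerates every candidate selection of distinct events of the exact size an
algorithm requires, applies the slot and diagnosis-separation rules directly,
and takes the earliest-finishing satisfying selection.
"""

from __future__ import annotations

import datetime as dt
from itertools import combinations

from msprev.records import DIAGNOSIS_TYPES, EventType, ObservationWindow

SEPARATION = 30
FIRST_SLOT = set(DIAGNOSIS_TYPES) | {EventType.DMT_SPECIFIC}
NON_INPATIENT_DX = {EventType.DX_OUTPATIENT_OTHER, EventType.DX_PRIMARY_CARE}


def _separation_ok(selection) -> bool:
    diagnoses = [d for d, t in selection if t in DIAGNOSIS_TYPES]
    return all(abs((a - b).days) >= SEPARATION for a, b in combinations(diagnoses, 2))


def oracle_evaluate(
    algorithm_id: str,
    events,
    window: ObservationWindow | None = None,
) -> dt.date | None:
    distinct = sorted(
        {
            (d, EventType(t))
            for d, t in events
            if window is None or window.start <= d <= window.end
        }
    )
    if algorithm_id == "MS1":
        selections = [s for s in combinations(distinct, 1) if s[0][1] in FIRST_SLOT]
    elif algorithm_id == "MS2":
        selections = [
            s
            for s in combinations(distinct, 2)
            if any(t in FIRST_SLOT for _, t in s) and _separation_ok(s)
        ]
    elif algorithm_id == "MS3":
        selections = [
            s
            for s in combinations(distinct, 3)
            if any(t in FIRST_SLOT for _, t in s) and _separation_ok(s)
        ]
    elif algorithm_id == "MS4":
        selections = [
            s for s in combinations(distinct, 1) if s[0][1] is EventType.DX_INPATIENT
        ]
        selections += [
            s
            for s in combinations(distinct, 2)
            if all(t in NON_INPATIENT_DX for _, t in s) and _separation_ok(s)
        ]
    elif algorithm_id == "MS5":
        selections = [
            s
            for s in combinations(distinct, 2)
            if all(t in DIAGNOSIS_TYPES for _, t in s) and _separation_ok(s)
        ]
    else:
        raise ValueError(algorithm_id)
    finish_dates = [max(d for d, _ in s) for s in selections]
    return min(finish_dates) if finish_dates else None


def random_stream(rng, max_events: int = 8):
    """A small random event stream; date spans chosen to stress the 30-day rule."""
    n = int(rng.integers(0, max_events + 1))
    span = int(rng.choice([45, 90, 400]))
    base = dt.date(2010, 1, 1)
    days = rng.integers(0, span, n)
    types = rng.choice([e.value for e in EventType], n)
    return [(base + dt.timedelta(int(d)), EventType(t)) for d, t in zip(days, types)]
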