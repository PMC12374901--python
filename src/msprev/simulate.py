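"""Synthetic source generator.

Emulates the statistical structure the analysis assumes, per data-source
profile: an age-structured female population aged 15-49, MS status assigned
from an age-prevalence curve, an age-at-onset distribution, MS-related
diagnoses and DMT dispensings as homogeneous Poisson processes from onset
onward, rare false-positive events in non-MS women, pregnancy episodes for
pregnant-only sources, and per-source masking of unavailable event types and
out-of-bounds dates.  A truth table records each woman's simulated status so
algorithm performance can be measured.

All randomness flows through one numpy Generator seeded from the config; the
draw order is fixed, so a fixed seed reproduces the output byte for byte.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .algorithms import ALGORITHM_IDS
from .cohort import GLOBAL_END, GLOBAL_START
from .profiles import DataSourceProfile, PopulationType
from .records import DIAGNOSIS_TYPES, EventType

_DAY = np.timedelta64(1, "D")
DAYS_PER_YEAR = 365.25

#: default MS prevalence per 100,000 by age group — rising with age, the
#: gradient real female populations show; the exact levels are arbitrary.
DEFAULT_AGE_PREVALENCE = [
    (15, 24, 40.0),
    (25, 29, 120.0),
    (30, 34, 200.0),
    (35, 39, 280.0),
    (40, 49, 360.0),
]

#: default annual event rates for a woman with MS, events/person-year
DEFAULT_MS_EVENT_RATES = {
    EventType.DX_INPATIENT.value: 0.3,
    EventType.DX_OUTPATIENT_OTHER.value: 0.8,
    EventType.DX_PRIMARY_CARE.value: 0.8,
    EventType.DMT_SPECIFIC.value: 1.5,
    EventType.DMT_NONSPECIFIC.value: 0.3,
}


class SimulationConfig(BaseModel):
    n_women: int = Field(gt=0)
    seed: int = 0
    birth_year_range: tuple[int, int] = (1957, 2003)
    #: annual hazard of leaving the source (emigration); joining is at birth
    annual_leave_rate: float = 0.005
    #: (age_low, age_high, prevalence per 100,000)
    age_prevalence_curve: list[tuple[int, int, float]] = DEFAULT_AGE_PREVALENCE
    event_rates_ms: dict[str, float] = DEFAULT_MS_EVENT_RATES
    false_positive_dx_rate: float = 0.0002
    false_positive_dmt_rate: float = 0.0001
    #: pregnancies per woman-year of in-study fertile follow-up
    pregnancy_rate: float = 0.08
    onset_age_mean: float = 29.0
    onset_age_sd: float = 7.0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ValueError("birth_year_range must be ordered")
        for low, high, prev in self.age_prevalence_curve:
            if not 0 <= prev <= 100_000:
                raise ValueError("prevalence must lie in [0, 100000] per 100,000")
            if low > high:
                raise ValueError("age group bounds must be ordered")
        rates = list(self.event_rates_ms.values()) + [
            self.false_positive_dx_rate,
            self.false_positive_dmt_rate,
            self.pregnancy_rate,
            self.annual_leave_rate,
        ]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        return self


def _ts(day: np.datetime64 | pd.Timestamp) -> np.datetime64:
    return np.datetime64(pd.Timestamp(day), "D")


def _uniform_days(rng, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Uniform dates (day resolution) in closed per-element [start, end]."""
    span = (end - start) / _DAY + 1
    offsets = np.floor(rng.random(len(start)) * span).astype("int64")
    return start + offsets * _DAY


def _prevalence_by_age(config: SimulationConfig, ages: np.ndarray) -> np.ndarray:
    """Per-woman MS probability from the age-prevalence curve.

    Ages outside every group clamp to the nearest group's level.
    """
    curve = sorted(config.age_prevalence_curve)
    p = np.full(len(ages), curve[0][2] / 1e5)
    for low, high, prev in curve:
        p[ages >= low] = prev / 1e5
    p[ages > curve[-1][1] + 1] = curve[-1][2] / 1e5
    return p


def _poisson_events(
    rng,
    rate: float,
    start: np.ndarray,
    end: np.ndarray,
    person_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Poisson process per woman over [start, end].

    Returns (person indices, event dates); counts are Poisson with mean
    rate * span-years, dates uniform within the span.
    """
    years = np.maximum((end - start) / _DAY + 1, 0) / DAYS_PER_YEAR
    counts = rng.poisson(rate * years)
    owners = np.repeat(np.arange(len(start)), counts)
    dates = _uniform_days(rng, np.repeat(start, counts), np.repeat(end, counts))
    return person_idx[owners], dates


def simulate(
    config: SimulationConfig,
    profile: DataSourceProfile,
    mask_availability: bool = True,
) -> dict[str, pd.DataFrame]:
    """Generate persons, events, pregnancies and a truth table for a source.

    With ``mask_availability`` (default) events the source cannot observe are
    dropped, emulating the per-source component availability; pass False to
    keep the full underlying stream and apply :func:`apply_availability`
    later (e.g. to compare sources on one stream).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_women
    study_start = _ts(max(profile.study_start, GLOBAL_START))
    study_end = _ts(min(profile.study_end, GLOBAL_END))

    # demographics
    y0, y1 = config.birth_year_range
    b_lo, b_hi = np.datetime64(f"{y0}-01-01", "D"), np.datetime64(f"{y1}-12-31", "D")
    birth = _uniform_days(rng, np.full(n, b_lo), np.full(n, b_hi))
    leave_years = (
        rng.exponential(1.0 / config.annual_leave_rate, n)
        if config.annual_leave_rate > 0
        else np.full(n, np.inf)
    )
    # cap far beyond the study horizon; avoids datetime64 overflow at inf
    leave_offset = np.minimum(
        np.where(np.isinf(leave_years), 1e6, leave_years * DAYS_PER_YEAR), 1e6
    ).astype("int64")
    leave = study_start + leave_offset * _DAY
    leave_absent = leave > study_end

    # disease status from the age-prevalence curve at the study midpoint
    ref_day = study_start + ((study_end - study_start) / _DAY).astype("int64") // 2 * _DAY
    age_ref = (ref_day - birth) / _DAY / DAYS_PER_YEAR
    p_ms = _prevalence_by_age(config, age_ref)
    ms_true = rng.random(n) < p_ms
    onset_age = np.clip(
        rng.normal(config.onset_age_mean, config.onset_age_sd, n), 10.0, age_ref
    )
    onset = birth + (onset_age * DAYS_PER_YEAR).astype("int64") * _DAY
    onset[~ms_true] = np.datetime64("NaT")

    ident_start = _ts(profile.identification_start)
    idx = np.arange(n)

    # disease-driven events, one Poisson process per event type from onset
    event_pids: list[np.ndarray] = []
    event_dates: list[np.ndarray] = []
    event_types: list[np.ndarray] = []
    ms_idx = idx[ms_true]
    if len(ms_idx):
        start = np.maximum(onset[ms_true].astype("datetime64[D]"), ident_start)
        end = np.minimum(np.full(len(ms_idx), study_end), leave[ms_true])
        ok = start <= end
        for etype in EventType:
            rate = config.event_rates_ms.get(etype.value, 0.0)
            if rate <= 0:
                continue
            pid, dates = _poisson_events(rng, rate, start[ok], end[ok], ms_idx[ok])
            event_pids.append(pid)
            event_dates.append(dates)
            event_types.append(np.full(len(pid), etype.value, dtype=object))

    # false positives in non-MS women (miscodings, off-label DMT use)
    neg_idx = idx[~ms_true]
    if len(neg_idx):
        start = np.full(len(neg_idx), ident_start)
        end = np.minimum(np.full(len(neg_idx), study_end), leave[~ms_true])
        ok = start <= end
        for rate, pool in (
            (config.false_positive_dx_rate, sorted(t.value for t in DIAGNOSIS_TYPES)),
            (config.false_positive_dmt_rate,
             [EventType.DMT_SPECIFIC.value, EventType.DMT_NONSPECIFIC.value]),
        ):
            if rate <= 0:
                continue
            pid, dates = _poisson_events(rng, rate, start[ok], end[ok], neg_idx[ok])
            kinds = rng.integers(0, len(pool), len(pid))
            event_pids.append(pid)
            event_dates.append(dates)
            event_types.append(np.array(pool, dtype=object)[kinds])

    # pregnancies (drawn for every source; only pregnant-only sources use them)
    pregnancies = _draw_pregnancies(rng, config, birth, study_start, study_end)

    person_ids = np.array([f"W{i:07d}" for i in range(n)])
    persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "birth_date": pd.to_datetime(birth),
            "death_date": pd.NaT,
            "source_join_date": pd.to_datetime(birth),
            "source_leave_date": pd.to_datetime(np.where(leave_absent, np.datetime64("NaT"), leave)),
        }
    )
    if event_pids:
        events = pd.DataFrame(
            {
                "person_id": person_ids[np.concatenate(event_pids)],
                "event_date": pd.to_datetime(np.concatenate(event_dates)),
                "event_type": np.concatenate(event_types),
            }
        ).sort_values(["person_id", "event_date", "event_type"], ignore_index=True)
    else:
        events = pd.DataFrame(columns=["person_id", "event_date", "event_type"])
    pregnancies["person_id"] = person_ids[pregnancies.pop("person_idx").to_numpy()]
    pregnancies = pregnancies[["person_id", "lmp_date", "end_date"]]
    truth = pd.DataFrame(
        {
            "person_id": person_ids,
            "ms_true": ms_true,
            "onset_date": pd.to_datetime(onset),
        }
    )
    tables = {
        "persons": persons,
        "events": events,
        "pregnancies": pregnancies,
        "truth": truth,
    }
    if mask_availability:
        tables["events"] = apply_availability(events, profile, pregnancies)
    return tables


def _draw_pregnancies(rng, config, birth, study_start, study_end) -> pd.DataFrame:
    """Non-overlapping pregnancy episodes within each woman's fertile in-study span."""
    n = len(birth)
    if config.pregnancy_rate <= 0:
        return pd.DataFrame({"person_idx": pd.Series(dtype="int64"),
                             "lmp_date": pd.Series(dtype="datetime64[ns]"),
                             "end_date": pd.Series(dtype="datetime64[ns]")})
    fert_lo = np.maximum(birth + int(15 * DAYS_PER_YEAR) * _DAY, study_start)
    fert_hi = np.minimum(birth + int(49 * DAYS_PER_YEAR) * _DAY, study_end - 310 * _DAY)
    ok = fert_lo <= fert_hi
    owners, lmp = _poisson_events(
        rng, config.pregnancy_rate, fert_lo[ok], fert_hi[ok], np.arange(n)[ok]
    )
    duration = np.clip(rng.normal(280.0, 14.0, len(lmp)), 180, 310).astype("int64")
    end = lmp + duration * _DAY
    df = pd.DataFrame({"person_idx": owners, "lmp_date": lmp, "end_date": end})
    df = df.sort_values(["person_idx", "lmp_date"], ignore_index=True)
    keep = np.ones(len(df), dtype=bool)
    last_end: dict[int, np.datetime64] = {}
    for i, (pid, s, e) in enumerate(zip(df["person_idx"], df["lmp_date"], df["end_date"])):
        prev = last_end.get(pid)
        if prev is not None and s <= prev:
            keep[i] = False
        else:
            last_end[pid] = e
    df = df[keep].reset_index(drop=True)
    df["lmp_date"] = pd.to_datetime(df["lmp_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


def apply_availability(
    events: pd.DataFrame,
    profile: DataSourceProfile,
    pregnancies: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Drop events the source cannot observe.

    Unavailable categories and dates outside [identification start, study
    end] are removed; for pregnant-only sources, events are further confined
    to the margin-extended pregnancy windows of their person.
    """
    if events.empty:
        return events.copy()
    allowed = {e.value for e in profile.available_event_types()}
    keep = events["event_type"].isin(allowed)
    keep &= events["event_date"] >= pd.Timestamp(profile.identification_start)
    keep &= events["event_date"] <= pd.Timestamp(profile.study_end)
    out = events[keep]
    if profile.population_type is PopulationType.PREGNANT_ONLY:
        if pregnancies is None or pregnancies.empty:
            return out.iloc[0:0].copy()
        windows = pregnancies.copy()
        windows["start"] = windows["lmp_date"] - pd.Timedelta(days=profile.pre_lmp_margin_days)
        windows["end"] = windows["end_date"] + pd.Timedelta(days=profile.post_pregnancy_margin_days)
        merged = out.reset_index().merge(
            windows[["person_id", "start", "end"]], on="person_id", how="inner"
        )
        inside = merged[
            (merged["event_date"] >= merged["start"]) & (merged["event_date"] <= merged["end"])
        ]
        out = out.loc[sorted(inside["index"].unique())]
    return out.reset_index(drop=True)


def simulate_pregnant_subset(
    config: SimulationConfig,
    profile: DataSourceProfile,
    mask_availability: bool = True,
) -> dict[str, pd.DataFrame]:
    """Simulate a pregnant-only source (events confined to pregnancy windows)."""
    if profile.population_type is not PopulationType.PREGNANT_ONLY:
        raise ValueError("simulate_pregnant_subset requires a pregnant_only profile")
    return simulate(config, profile, mask_availability=mask_availability)


def algorithm_performance(truth: pd.DataFrame, ident: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity and specificity of each algorithm against the truth table."""
    positive = set(truth.loc[truth["ms_true"], "person_id"])
    negative = set(truth.loc[~truth["ms_true"], "person_id"])
    rows = []
    for alg in ALGORITHM_IDS:
        flagged = set(ident.loc[ident["algorithm_id"] == alg, "person_id"])
        tp = len(flagged & positive)
        fp = len(flagged & negative)
        rows.append(
            {
                "algorithm_id": alg,
                "sensitivity": tp / len(positive) if positive else float("nan"),
                "specificity": 1 - fp / len(negative) if negative else float("nan"),
                "true_positives": tp,
                "false_positives": fp,
            }
        )
    return pd.DataFrame(rows)
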