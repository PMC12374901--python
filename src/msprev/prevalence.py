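"""Prevalence estimation, stratification, summary metrics and masking.

Two estimators, matched to the source regime:

* **Average point prevalence** (childbearing-age sources): on the first day
  of each month the point prevalence is the number of women in study and
  identified with MS on or before that day, over the number of women in
  study that day; the period estimate is the unweighted mean of those
  monthly ratios.
* **Period prevalence** (pregnant-only sources, where identification dates
  are anchored to pregnancies and poorly reflect diagnosis timing): everyone
  observed at any time in the period forms the denominator, and those
  identified by the period's end form the numerator.

Both are reported per 100,000 with 95% Wilson score intervals, stratified by
calendar period and by age group.  Small non-zero case counts (1-4) are
masked in exported tables, mirroring the disclosure rules of federated
health-data networks.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .algorithms import ALGORITHM_IDS
from .profiles import DataSourceProfile
from .util import add_years_series, round_half_away

#: exported cells with 1 <= cases <= 4 are suppressed
MASK_THRESHOLD = 5

DEFAULT_PERIODS = [(2005, 2009), (2010, 2014), (2015, 2019)]
DEFAULT_AGE_GROUPS = [(15, 24), (25, 29), (30, 34), (35, 39), (40, 49)]


def wilson_ci(k: float, n: float, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Centre (k + z^2/2)/(n + z^2), half-width z*sqrt(k(n-k)/n + z^2/4)/(n + z^2).
    Accepts fractional effective counts.  The lower bound is exactly 0 at
    k = 0 and the upper exactly 1 at k = n.
    """
    if n <= 0:
        raise ValueError("wilson_ci requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError("wilson_ci requires 0 <= k <= n")
    z = norm.ppf((1.0 + confidence) / 2.0)
    z2 = z * z
    denom = n + z2
    centre = (k + z2 / 2.0) / denom
    half = z * math.sqrt(k * (n - k) / n + z2 / 4.0) / denom
    low = 0.0 if k == 0 else max(0.0, centre - half)
    high = 1.0 if k == n else min(1.0, centre + half)
    return low, high


@dataclass(frozen=True)
class PrevalenceEstimate:
    period_label: str
    age_label: str | None
    algorithm_id: str
    numerator: float  # mean monthly cases (average point) or case count (period)
    denominator: float
    prevalence_per_100k: float
    ci_low_per_100k: float
    ci_high_per_100k: float
    n_points: int = 1  # monthly points averaged (1 for period prevalence)

    @property
    def masked(self) -> bool:
        return 0 < self.numerator < MASK_THRESHOLD


@dataclass(frozen=True)
class StratumScheme:
    """Calendar periods and age groups over which prevalence is stratified."""

    periods: Sequence[tuple[int, int]] = tuple(DEFAULT_PERIODS)
    age_groups: Sequence[tuple[int, int]] = tuple(DEFAULT_AGE_GROUPS)

    def clipped_periods(self, profile: DataSourceProfile) -> list[tuple[dt.date, dt.date, str]]:
        """Periods intersected with the profile's study span, with labels."""
        out = []
        for y0, y1 in self.periods:
            start = max(dt.date(y0, 1, 1), profile.study_start)
            end = min(dt.date(y1, 12, 31), profile.study_end)
            if start <= end:
                label = str(start.year) if start.year == end.year else f"{start.year}-{end.year}"
                out.append((start, end, label))
        return out


def month_firsts(period_start: dt.date, period_end: dt.date) -> list[pd.Timestamp]:
    """First days of months within the closed period [start, end]."""
    first = dt.date(period_start.year, period_start.month, 1)
    if first < period_start:
        first = (pd.Timestamp(first) + pd.offsets.MonthBegin(1)).date()
    return list(pd.date_range(first, period_end, freq="MS"))


def _age_mask(
    birth_dates: pd.Series, day: pd.Timestamp, age_group: tuple[int, int]
) -> np.ndarray:
    """Completed age on ``day`` within the closed [low, high] group."""
    low, high = age_group
    lower = add_years_series(birth_dates, low)
    upper = add_years_series(birth_dates, high + 1)
    return ((lower <= day) & (day < upper)).to_numpy()


def _ident_for(cohort: pd.DataFrame, ident: pd.Series) -> np.ndarray:
    """Identification dates aligned to cohort rows (NaT when never identified)."""
    return pd.to_datetime(cohort["person_id"].map(ident)).to_numpy()


def point_prevalence(
    cohort: pd.DataFrame,
    ident: pd.Series,
    day: dt.date | pd.Timestamp,
    age_group: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """(numerator, denominator) on a single day for one algorithm.

    ``ident`` maps person_id to identification date.  The denominator counts
    women whose follow-up contains the day (and who are in the age group that
    day); the numerator counts those identified on or before the day.
    """
    day = pd.Timestamp(day)
    in_study = (cohort["entry_date"] <= day) & (cohort["exit_date"] >= day)
    mask = in_study.to_numpy()
    if age_group is not None:
        mask &= _age_mask(cohort["birth_date"], day, age_group)
    ident_dates = _ident_for(cohort, ident)
    identified = ident_dates <= day.to_datetime64()  # NaT compares False
    return int((mask & identified).sum()), int(mask.sum())


def average_point_prevalence(
    cohort: pd.DataFrame,
    ident: pd.Series,
    period: tuple[dt.date, dt.date],
    age_group: tuple[int, int] | None = None,
    period_label: str | None = None,
    algorithm_id: str = "",
    confidence: float = 0.95,
) -> PrevalenceEstimate | None:
    """Mean of monthly point prevalences over the period, with Wilson CI.

    The CI uses effective counts: n_eff is the mean monthly denominator and
    k_eff = p_hat * n_eff, so the interval always contains the reported
    estimate and reduces to the plain Wilson interval for a static cohort.
    Months with an empty denominator are skipped; None when all are.
    """
    # align person-level arrays once; the month loop is then pure numpy
    entry = cohort["entry_date"].to_numpy()
    exit_ = cohort["exit_date"].to_numpy()
    ident_dates = _ident_for(cohort, ident)
    if age_group is not None:
        low_bound = add_years_series(cohort["birth_date"], age_group[0]).to_numpy()
        high_bound = add_years_series(cohort["birth_date"], age_group[1] + 1).to_numpy()
    ks: list[int] = []
    ns: list[int] = []
    for day in month_firsts(*period):
        d = day.to_datetime64()
        mask = (entry <= d) & (exit_ >= d)
        if age_group is not None:
            mask &= (low_bound <= d) & (d < high_bound)
        n = int(mask.sum())
        if n > 0:
            ks.append(int((mask & (ident_dates <= d)).sum()))
            ns.append(n)
    if not ns:
        return None
    p_hat = float(np.mean([k / n for k, n in zip(ks, ns)]))
    n_eff = float(np.mean(ns))
    low, high = wilson_ci(p_hat * n_eff, n_eff, confidence)
    return PrevalenceEstimate(
        period_label=period_label or f"{period[0].year}-{period[1].year}",
        age_label=None if age_group is None else f"{age_group[0]}-{age_group[1]}",
        algorithm_id=algorithm_id,
        numerator=float(np.mean(ks)),
        denominator=n_eff,
        prevalence_per_100k=p_hat * 1e5,
        ci_low_per_100k=low * 1e5,
        ci_high_per_100k=high * 1e5,
        n_points=len(ns),
    )


def _period_denominator_ids(
    cohort: pd.DataFrame,
    windows: pd.DataFrame,
    period: tuple[dt.date, dt.date],
    age_group: tuple[int, int] | None,
) -> pd.Index:
    """Persons observed at any time during the period (in the age group then)."""
    start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    w = windows
    lo = w["start"].clip(lower=start)
    hi = w["end"].clip(upper=end)
    if age_group is not None:
        birth = w["person_id"].map(cohort.set_index("person_id")["birth_date"])
        lo = np.maximum(lo, add_years_series(birth, age_group[0]))
        hi = np.minimum(hi, add_years_series(birth, age_group[1] + 1) - pd.Timedelta(days=1))
    return pd.Index(w.loc[(lo <= hi).to_numpy(), "person_id"].unique())


def period_prevalence(
    cohort: pd.DataFrame,
    windows: pd.DataFrame,
    ident: pd.Series,
    period: tuple[dt.date, dt.date],
    age_group: tuple[int, int] | None = None,
    period_label: str | None = None,
    algorithm_id: str = "",
    confidence: float = 0.95,
) -> PrevalenceEstimate | None:
    """Period prevalence: observed any time in the period; identified by its end."""
    ids = _period_denominator_ids(cohort, windows, period, age_group)
    n = len(ids)
    if n == 0:
        return None
    ident_dates = pd.to_datetime(pd.Series(list(ids)).map(ident))
    k = int((ident_dates <= pd.Timestamp(period[1])).sum())
    low, high = wilson_ci(k, n, confidence)
    return PrevalenceEstimate(
        period_label=period_label or f"{period[0].year}-{period[1].year}",
        age_label=None if age_group is None else f"{age_group[0]}-{age_group[1]}",
        algorithm_id=algorithm_id,
        numerator=float(k),
        denominator=float(n),
        prevalence_per_100k=k / n * 1e5,
        ci_low_per_100k=low * 1e5,
        ci_high_per_100k=high * 1e5,
    )


# ---------------------------------------------------------------------------
# Population-level summary (per-algorithm counts and derived metrics)


def max_relative_difference(counts: Mapping[str, int]) -> float | None:
    """100 * (max - min) / max over the per-algorithm case counts.

    None when every count is zero (undefined).
    """
    values = list(counts.values())
    top = max(values)
    if top == 0:
        return None
    return 100.0 * (top - min(values)) / top


def summarize_counts(counts: Mapping[str, int], population: int) -> pd.DataFrame:
    """Case counts with percentages of the study population (2 dp)."""
    rows = []
    for alg, count in counts.items():
        pct = 100.0 * count / population if population else float("nan")
        rows.append(
            {
                "algorithm_id": alg,
                "cases": count,
                "pct_of_population": pct,
                "pct_rounded": round_half_away(pct, 2),
            }
        )
    return pd.DataFrame(rows)


def overlap_shares(ident: pd.DataFrame) -> pd.DataFrame:
    """Pairwise overlap 100 * |A and B| / |A| between algorithm case sets.

    ``ident`` is the long identification table.  Row = A, column = B.
    """
    sets = {
        alg: set(ident.loc[ident["algorithm_id"] == alg, "person_id"]) for alg in ALGORITHM_IDS
    }
    data = {
        a: [100.0 * len(sets[a] & sets[b]) / len(sets[a]) if sets[a] else float("nan")
            for b in ALGORITHM_IDS]
        for a in ALGORITHM_IDS
    }
    return pd.DataFrame(data, index=pd.Index(ALGORITHM_IDS, name="B")).T


@dataclass
class PopulationSummary:
    population: int
    counts: dict[str, int]
    percentages: pd.DataFrame
    max_relative_difference: float | None
    overlap: pd.DataFrame = field(repr=False)


def table3_summary(cohort: pd.DataFrame, ident: pd.DataFrame) -> PopulationSummary:
    """Per-algorithm case counts, population percentages, spread, overlap."""
    counts = {
        alg: int(ident.loc[ident["algorithm_id"] == alg, "person_id"].nunique())
        for alg in ALGORITHM_IDS
    }
    population = len(cohort)
    return PopulationSummary(
        population=population,
        counts=counts,
        percentages=summarize_counts(counts, population),
        max_relative_difference=max_relative_difference(counts),
        overlap=overlap_shares(ident),
    )


# ---------------------------------------------------------------------------
# Masking


def mask(estimate: PrevalenceEstimate) -> PrevalenceEstimate:
    """Identity on the estimate; the masked flag derives from the numerator."""
    return replace(estimate)


def estimates_frame(estimates: Sequence[PrevalenceEstimate], masked_export: bool = False
                    ) -> pd.DataFrame:
    """Tabulate estimates; with ``masked_export`` small cells are suppressed.

    Masked rows (1-4 cases) keep their stratum labels and flag but blank the
    numerator, estimate and CI.  Zero and >= 5 pass through.
    """
    rows = []
    for est in estimates:
        row = {
            "period": est.period_label,
            "age_group": est.age_label or "",
            "algorithm_id": est.algorithm_id,
            "numerator": est.numerator,
            "denominator": est.denominator,
            "prevalence_per_100k": est.prevalence_per_100k,
            "ci_low_per_100k": est.ci_low_per_100k,
            "ci_high_per_100k": est.ci_high_per_100k,
            "n_points": est.n_points,
            "masked": est.masked,
        }
        if masked_export and est.masked:
            for col in ("numerator", "prevalence_per_100k", "ci_low_per_100k",
                        "ci_high_per_100k"):
                row[col] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
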