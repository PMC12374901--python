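"""End-to-end pipeline: load or simulate a source, build the cohort, run the
five identification algorithms, estimate prevalence, and export masked report
tables with a run log of counts at each filter step."""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, model_validator

from . import io as msio
from .algorithms import ALGORITHM_IDS, identify_cohort
from .cohort import build_cohort
from .prevalence import (
    MASK_THRESHOLD,
    PopulationSummary,
    PrevalenceEstimate,
    StratumScheme,
    average_point_prevalence,
    estimates_frame,
    period_prevalence,
    table3_summary,
)
from .profiles import DataSourceProfile, PopulationType, get_preset
from .simulate import SimulationConfig, simulate

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    input_mode: Literal["synthetic", "files"]
    output_dir: Path
    preset: str | None = None
    profile_path: Path | None = None
    data_dir: Path | None = None
    seed: int = 0
    n_women: int = 20_000
    strict: bool = True
    sim: SimulationConfig | None = None
    scheme: StratumScheme | None = None

    model_config = {"arbitrary_types_allowed": True}

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.preset is None and self.profile_path is None:
            raise ValueError("either preset or profile_path is required")
        if self.input_mode == "files" and self.data_dir is None:
            raise ValueError("files mode requires data_dir")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def resolve_profile(self) -> DataSourceProfile:
        if self.profile_path is not None:
            return DataSourceProfile.from_json(self.profile_path)
        return get_preset(self.preset)


@dataclass
class RunResult:
    profile: DataSourceProfile
    cohort: pd.DataFrame
    windows: pd.DataFrame
    identifications: pd.DataFrame
    period_estimates: list[PrevalenceEstimate]
    age_estimates: list[PrevalenceEstimate]
    summary: PopulationSummary
    log: dict = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def _estimate_all(
    profile: DataSourceProfile,
    cohort: pd.DataFrame,
    windows: pd.DataFrame,
    ident: pd.DataFrame,
    scheme: StratumScheme,
) -> tuple[list[PrevalenceEstimate], list[PrevalenceEstimate]]:
    """Period-stratified estimates plus age-stratified ones for the latest period.

    The estimator follows the population type: average point prevalence for
    childbearing-age sources, period prevalence for pregnant-only sources.
    """
    by_alg = {
        alg: ident.loc[ident["algorithm_id"] == alg].set_index("person_id")[
            "identification_date"
        ]
        for alg in ALGORITHM_IDS
    }
    periods = scheme.clipped_periods(profile)
    span = (
        max(profile.study_start, dt.date(2005, 1, 1)),
        min(profile.study_end, dt.date(2019, 12, 31)),
    )
    overall_label = f"{span[0].year}-{span[1].year} (overall)"
    point_based = profile.population_type is PopulationType.CHILDBEARING_AGE

    def one(alg, period, label, age_group=None):
        if point_based:
            return average_point_prevalence(
                cohort, by_alg[alg], period, age_group, label, alg
            )
        return period_prevalence(
            cohort, windows, by_alg[alg], period, age_group, label, alg
        )

    period_estimates = [
        est
        for alg in ALGORITHM_IDS
        for start, end, label in periods
        if (est := one(alg, (start, end), label)) is not None
    ]
    period_estimates += [
        est
        for alg in ALGORITHM_IDS
        if (est := one(alg, span, overall_label)) is not None
    ]
    age_estimates = []
    if periods:
        start, end, label = periods[-1]  # the most recent, longest-lookback period
        age_estimates = [
            est
            for alg in ALGORITHM_IDS
            for group in scheme.age_groups
            if (est := one(alg, (start, end), label, group)) is not None
        ]
    return period_estimates, age_estimates


def _masked_table3(summary: PopulationSummary) -> pd.DataFrame:
    df = summary.percentages.copy()
    df["masked"] = (df["cases"] > 0) & (df["cases"] < MASK_THRESHOLD)
    for col in ("cases", "pct_of_population", "pct_rounded"):
        df[col] = df[col].where(~df["masked"])
    df["population"] = summary.population
    mrd = summary.max_relative_difference
    df["max_relative_difference_pct"] = float("nan") if mrd is None else mrd
    return df


def run(config: RunConfig) -> RunResult:
    """Execute the configured pipeline and write report files.

    Emits cohort.csv, identifications.csv, prevalence tables (masked),
    table3_summary.csv, run_log.json and summary.txt into the output
    directory.  Partial outputs are removed if a stage fails.
    """
    profile = config.resolve_profile()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_inner(config, profile, out_dir, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run_inner(
    config: RunConfig, profile: DataSourceProfile, out_dir: Path, written: list[Path]
) -> RunResult:
    log: dict = {"profile": profile.name, "population_type": profile.population_type.value}
    if config.input_mode == "synthetic":
        sim = config.sim or SimulationConfig(n_women=config.n_women, seed=config.seed)
        tables = simulate(sim, profile)
        log["input"] = "synthetic"
    else:
        tables = msio.read_tables(config.data_dir, profile=profile, strict=config.strict)
        log["input"] = str(config.data_dir)
    log["n_persons"] = len(tables["persons"])
    log["n_events"] = len(tables["events"])
    log["n_pregnancies"] = len(tables["pregnancies"])

    cohort, windows = build_cohort(tables["persons"], tables["pregnancies"], profile)
    log["n_eligible"] = len(cohort)
    if len(cohort):
        log["mean_coverage"] = float(cohort["coverage"].mean())
        log["median_follow_up_years"] = float(
            cohort["follow_up_days"].median() / 365.25
        )

    events = tables["events"]
    events = events[events["person_id"].isin(set(cohort["person_id"]))]
    log["n_events_in_cohort"] = len(events)
    log["n_women_with_events"] = int(events["person_id"].nunique())

    ident = identify_cohort(events, profile)
    summary = table3_summary(cohort, ident)
    log["n_identified"] = summary.counts

    scheme = config.scheme or StratumScheme()
    period_estimates, age_estimates = _estimate_all(profile, cohort, windows, ident, scheme)

    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        written.append(path)
        paths[name.removesuffix(".csv")] = path

    cohort_out = cohort.copy()
    for col in ("birth_date", "entry_date", "exit_date"):
        cohort_out[col] = cohort_out[col].dt.strftime("%Y-%m-%d")
    emit("cohort.csv", cohort_out[
        ["person_id", "entry_date", "exit_date", "n_windows", "coverage"]
    ])
    ident_out = ident.copy()
    if len(ident_out):
        ident_out["identification_date"] = ident_out["identification_date"].dt.strftime(
            "%Y-%m-%d"
        )
    emit("identifications.csv", ident_out)
    estimator = (
        "average_point_prevalence"
        if profile.population_type is PopulationType.CHILDBEARING_AGE
        else "period_prevalence"
    )
    log["estimator"] = estimator
    emit("prevalence_by_period.csv", estimates_frame(period_estimates, masked_export=True))
    emit("prevalence_by_age.csv", estimates_frame(age_estimates, masked_export=True))
    emit("table3_summary.csv", _masked_table3(summary))

    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str) + "\n")
    written.append(log_path)
    paths["run_log"] = log_path

    summary_path = out_dir / "summary.txt"
    summary_path.write_text(_text_summary(profile, log, summary, estimator))
    written.append(summary_path)
    paths["summary"] = summary_path

    return RunResult(
        profile=profile,
        cohort=cohort,
        windows=windows,
        identifications=ident,
        period_estimates=period_estimates,
        age_estimates=age_estimates,
        summary=summary,
        log=log,
        paths=paths,
    )


def _text_summary(
    profile: DataSourceProfile, log: dict, summary: PopulationSummary, estimator: str
) -> str:
    lines = [
        f"Source: {profile.name} ({profile.population_type.value})",
        f"Study period: {profile.study_start} to {profile.study_end}",
        f"Estimator: {estimator}",
        f"Eligible women: {log.get('n_eligible', 0)}",
    ]
    if "mean_coverage" in log:
        lines.append(f"Mean coverage: {log['mean_coverage']:.2%}")
    lines.append("Cases per algorithm (counts below 5 masked):")
    for alg in ALGORITHM_IDS:
        count = summary.counts.get(alg, 0)
        shown = "<5" if 0 < count < MASK_THRESHOLD else str(count)
        lines.append(f"  {alg}: {shown}")
    mrd = summary.max_relative_difference
    if mrd is not None:
        lines.append(f"Maximum relative difference between two algorithms: {mrd:.1f}%")
    return "\n".join(lines) + "\n"
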