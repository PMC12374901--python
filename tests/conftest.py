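import datetime as dt

import pandas as pd
import pytest

from msprev import DataSourceProfile, PopulationType


@pytest.fixture
def childbearing_profile() -> DataSourceProfile:
    """A full-availability childbearing-age source covering 2010-2014."""
    return DataSourceProfile(
        name="test_full",
        population_type=PopulationType.CHILDBEARING_AGE,
        study_start=dt.date(2010, 1, 1),
        study_end=dt.date(2014, 12, 31),
    )


@pytest.fixture
def long_profile() -> DataSourceProfile:
    """Full availability over the whole 2005-2019 horizon."""
    return DataSourceProfile(
        name="test_long",
        population_type=PopulationType.CHILDBEARING_AGE,
        study_start=dt.date(2005, 1, 1),
        study_end=dt.date(2019, 12, 31),
    )


@pytest.fixture
def pregnant_profile() -> DataSourceProfile:
    """Pregnant-only source, 90-day margins either side of each pregnancy."""
    return DataSourceProfile(
        name="test_pregnant",
        population_type=PopulationType.PREGNANT_ONLY,
        study_start=dt.date(2005, 1, 1),
        study_end=dt.date(2019, 12, 31),
        has_outpatient_other_dx=False,
        has_primary_care_dx=False,
        pre_lmp_margin_days=90,
        post_pregnancy_margin_days=90,
    )


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Cohort frame from compact dicts (dates as ISO strings)."""
    df = pd.DataFrame(rows)
    for col in ("birth_date", "entry_date", "exit_date"):
        df[col] = pd.to_datetime(df[col])
    df["n_windows"] = df.get("n_windows", 1)
    df["follow_up_days"] = (df["exit_date"] - df["entry_date"]).dt.days + 1
    df["observed_days"] = df["follow_up_days"]
    df["coverage"] = 1.0
    return df


def ident_series(mapping: dict[str, str | None]) -> pd.Series:
    """person_id -> identification date Series (None for never identified)."""
    return pd.Series(
        {pid: pd.Timestamp(date) for pid, date in mapping.items() if date is not None},
        dtype="datetime64[ns]",
    )
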