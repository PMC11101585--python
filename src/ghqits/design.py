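"""Study design: exposure periods, eligibility filters, time covariates.

The quasi-experiment divides Aug 1 2009 – Mar 23 2020 into three exposure
periods bounded by two interruptions: the coming into force of the 2014
Immigration Act (May 14 2014) and the start of mass media coverage of the
Windrush scandal (Nov 28 2017).  Interviews are assigned to periods by
their exact date; survey waves span 24 months and may straddle a boundary,
so wave numbers are descriptive only and dates are authoritative.

Eligibility mirrors the cohort-inclusion rules: respondents aged 16+ at
interview, with a complete GHQ-12 outcome in at least one wave, known sex
and year of birth, and belonging to one of the six in-scope ethnic groups.
Filters are applied in a fixed order and every removal is counted in an
:class:`ExclusionLog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the six in-scope ethnic groups; White is the comparison group
ETHNICITIES = [
    "White",
    "Black African",
    "Black Caribbean",
    "Indian",
    "Pakistani",
    "Bangladeshi",
]

STUDY_START = date(2009, 8, 1)
STUDY_END = date(2020, 3, 23)  # first COVID-19 lockdown

DAYS_PER_YEAR = 365.25
MIN_AGE = 16


@dataclass(frozen=True)
class ExposurePeriod:
    """One exposure period; both endpoint dates are inclusive."""

    index: int
    start_date: date
    end_date: date
    label: str = ""

    def contains(self, d: date) -> bool:
        return self.start_date <= d <= self.end_date


DEFAULT_PERIODS = [
    ExposurePeriod(1, date(2009, 8, 1), date(2014, 5, 13), "pre Immigration Act 2014"),
    ExposurePeriod(2, date(2014, 5, 14), date(2017, 11, 27), "post Immigration Act 2014"),
    ExposurePeriod(3, date(2017, 11, 28), date(2020, 3, 23), "post media coverage"),
]


def validate_periods(periods: list[ExposurePeriod]) -> None:
    """Check the periods partition the study window with no gaps/overlaps."""
    if not periods:
        raise ValueError("no exposure periods given")
    ordered = sorted(periods, key=lambda p: p.start_date)
    if [p.index for p in ordered] != list(range(1, len(ordered) + 1)):
        raise ValueError("period indices must be 1..k in date order")
    for p in ordered:
        if p.end_date < p.start_date:
            raise ValueError(f"period {p.index} ends before it starts")
    for a, b in zip(ordered, ordered[1:]):
        if (b.start_date - a.end_date).days != 1:
            raise ValueError(
                f"periods {a.index} and {b.index} do not abut: "
                f"{a.end_date} -> {b.start_date}"
            )


def assign_exposure_period(
    interview_date: date | str | pd.Timestamp,
    periods: list[ExposurePeriod] | None = None,
) -> int | None:
    """Map an interview date to its exposure period index.

    Returns ``None`` ("ineligible") for dates before the first period
    starts or after the last period ends.
    """
    periods = DEFAULT_PERIODS if periods is None else periods
    validate_periods(periods)
    if isinstance(interview_date, str):
        interview_date = pd.Timestamp(interview_date)  # raises on malformed input
    if isinstance(interview_date, pd.Timestamp):
        interview_date = interview_date.date()
    for p in periods:
        if p.contains(interview_date):
            return p.index
    return None


def assign_periods_frame(
    dates: pd.Series, periods: list[ExposurePeriod] | None = None
) -> pd.Series:
    """Vectorised period assignment; NaN marks ineligible dates."""
    periods = DEFAULT_PERIODS if periods is None else periods
    validate_periods(periods)
    d = pd.to_datetime(dates)
    out = pd.Series(np.nan, index=dates.index, dtype=float)
    for p in periods:
        mask = (d >= pd.Timestamp(p.start_date)) & (d <= pd.Timestamp(p.end_date))
        out[mask] = p.index
    return out


@dataclass
class ExclusionLog:
    """Counts of records and persons removed by each filter, in order."""

    steps: list[dict] = field(default_factory=list)

    def record(
        self,
        step: str,
        records_removed: int,
        persons_removed: int,
        records_remaining: int,
        persons_remaining: int,
    ) -> None:
        self.steps.append(
            {
                "step": step,
                "records_removed": int(records_removed),
                "persons_removed": int(persons_removed),
                "records_remaining": int(records_remaining),
                "persons_remaining": int(persons_remaining),
            }
        )
        logger.info(
            "filter %-28s removed %6d records / %6d persons "
            "(%d records, %d persons remain)",
            step,
            records_removed,
            persons_removed,
            records_remaining,
            persons_remaining,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def compute_time_covariates(
    rows: pd.DataFrame, periods: list[ExposurePeriod] | None = None
) -> pd.DataFrame:
    """Fill ``calendar_time`` and ``time_since_period`` (in years).

    ``calendar_time`` counts years since the study origin; the clock for
    ``time_since_period`` restarts at the start of the row's assigned
    exposure period.  A 365.25-day year keeps the scale leap-safe.
    """
    periods = DEFAULT_PERIODS if periods is None else periods
    out = rows.copy()
    d = pd.to_datetime(out["interview_date"])
    origin = pd.Timestamp(min(p.start_date for p in periods))
    out["calendar_time"] = (d - origin).dt.days / DAYS_PER_YEAR
    starts = {p.index: pd.Timestamp(p.start_date) for p in periods}
    period_start = pd.to_datetime(out["period"].map(lambda k: starts[int(k)]))
    out["time_since_period"] = (d - period_start).dt.days / DAYS_PER_YEAR
    return out


def apply_eligibility_filters(
    persons: pd.DataFrame,
    observations: pd.DataFrame,
    periods: list[ExposurePeriod] | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Filter a raw cohort into analysis rows.

    Filters run in a fixed order so the log is reproducible:

    1. drop interviews dated outside the exposure-period windows;
    2. drop interviews at which the respondent was under 16;
    3. drop interviews with an incomplete GHQ-12 outcome, then persons
       with no complete outcome in any wave;
    4. drop persons with missing sex or year of birth;
    5. drop persons outside the six in-scope ethnic groups.

    `observations` must already carry a ``ghq_total`` column (see
    :func:`ghqits.ghq.add_ghq_totals`); missing totals mark incomplete
    outcomes.  Returns the analysis rows (one per eligible
    person-interview, person attributes merged on, time covariates
    filled) and the exclusion log.
    """
    periods = DEFAULT_PERIODS if periods is None else periods
    validate_periods(periods)
    if "ghq_total" not in observations.columns:
        raise ValueError("observations lack a ghq_total column; score them first")

    log = ExclusionLog()
    obs = observations.copy()
    pers = persons.set_index("person_id", drop=False)

    def counts(o: pd.DataFrame) -> tuple[int, int]:
        return len(o), o["person_id"].nunique()

    n_rec, n_per = counts(obs)

    # 1. interviews outside the period windows
    obs["period"] = assign_periods_frame(obs["interview_date"], periods)
    keep = obs["period"].notna()
    obs = obs[keep]
    r, p = counts(obs)
    log.record("outside_period_windows", n_rec - r, n_per - p, r, p)
    n_rec, n_per = r, p

    # 2. under 16 at interview (age = interview year - birth year)
    birth_year = obs["person_id"].map(pers["birth_year"])
    interview_year = pd.to_datetime(obs["interview_date"]).dt.year
    age = interview_year - birth_year
    obs = obs[(age >= MIN_AGE) | birth_year.isna()]
    r, p = counts(obs)
    log.record("under_16_at_interview", n_rec - r, n_per - p, r, p)
    n_rec, n_per = r, p

    # 3. incomplete GHQ-12 outcomes; persons with none complete vanish here
    obs = obs[obs["ghq_total"].notna()]
    r, p = counts(obs)
    log.record("incomplete_ghq12_outcome", n_rec - r, n_per - p, r, p)
    n_rec, n_per = r, p

    # 4. persons with missing sex or year of birth
    bad_person = pers.index[pers["sex"].isna() | pers["birth_year"].isna()]
    obs = obs[~obs["person_id"].isin(bad_person)]
    r, p = counts(obs)
    log.record("missing_sex_or_birth_year", n_rec - r, n_per - p, r, p)
    n_rec, n_per = r, p

    # 5. out-of-scope ethnic groups
    eth = obs["person_id"].map(pers["ethnicity"])
    obs = obs[eth.isin(ETHNICITIES)]
    r, p = counts(obs)
    log.record("out_of_scope_ethnicity", n_rec - r, n_per - p, r, p)

    person_cols = [
        c for c in pers.columns if c not in obs.columns and c != "person_id"
    ]
    rows = obs.merge(
        pers[["person_id"] + person_cols].reset_index(drop=True),
        on="person_id",
        how="left",
    )
    rows["period"] = rows["period"].astype(int)
    rows["age"] = (
        pd.to_datetime(rows["interview_date"]).dt.year - rows["birth_year"]
    ).astype(int)
    rows = compute_time_covariates(rows, periods)
    rows = rows.sort_values(["person_id", "interview_date"], kind="mergesort")
    rows = rows.reset_index(drop=True)
    return rows, log
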