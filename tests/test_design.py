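"""Exposure-period assignment, eligibility filters and time covariates."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from ghqits import (
    DEFAULT_PERIODS,
    ExposurePeriod,
    add_ghq_totals,
    apply_eligibility_filters,
    assign_exposure_period,
    compute_time_covariates,
)
from ghqits.design import validate_periods
from ghqits.ghq import ITEM_COLUMNS


@pytest.mark.parametrize(
    "day,expected",
    [
        (date(2009, 8, 1), 1),
        (date(2014, 5, 13), 1),  # last day before the Immigration Act
        (date(2014, 5, 14), 2),  # Act comes into force
        (date(2017, 11, 27), 2),
        (date(2017, 11, 28), 3),  # media coverage begins
        (date(2020, 3, 23), 3),  # first COVID-19 lockdown
        (date(2020, 3, 24), None),
        (date(2009, 7, 31), None),
    ],
)
def test_period_assignment_at_boundaries(day, expected):
    assert assign_exposure_period(day) == expected


def test_every_study_date_maps_to_exactly_one_period():
    d = date(2009, 8, 1)
    step = timedelta(days=17)  # co-prime stride samples all weekdays/months
    while d <= date(2020, 3, 23):
        assert assign_exposure_period(d) in (1, 2, 3)
        d += step


def test_malformed_date_raises():
    with pytest.raises(ValueError):
        assign_exposure_period("not-a-date")


def test_gapped_or_overlapping_periods_rejected():
    gap = [
        ExposurePeriod(1, date(2009, 8, 1), date(2014, 5, 12)),
        ExposurePeriod(2, date(2014, 5, 14), date(2020, 3, 23)),
    ]
    with pytest.raises(ValueError):
        validate_periods(gap)
    overlap = [
        ExposurePeriod(1, date(2009, 8, 1), date(2014, 5, 14)),
        ExposurePeriod(2, date(2014, 5, 14), date(2020, 3, 23)),
    ]
    with pytest.raises(ValueError):
        validate_periods(overlap)


def test_time_covariates():
    rows = pd.DataFrame(
        {
            "interview_date": pd.to_datetime(
                ["2009-08-01", "2014-05-14", "2015-05-14"]
            ),
            "period": [1, 2, 2],
        }
    )
    out = compute_time_covariates(rows)
    assert out["calendar_time"].iloc[0] == 0.0
    assert out["time_since_period"].iloc[1] == 0.0
    assert out["time_since_period"].iloc[2] == pytest.approx(1.0, abs=1 / 365.25)
    assert (out["time_since_period"] >= 0).all()


def _toy_cohort():
    """Five persons exercising each filter."""
    persons = pd.DataFrame(
        {
            "person_id": [1, 2, 3, 4, 5],
            "ethnicity": [
                "White",
                "Black Caribbean",
                "Chinese",  # out of scope
                "White",
                "Indian",
            ],
            "stratum": [1] * 5,
            "area": [1] * 5,
            "sex": [0, 1, 0, np.nan, 1],  # person 4 missing sex
            "birth_year": [1999, 1970, 1980, 1960, 1990],  # person 1 aged 15 in 2014
        }
    )
    obs = pd.DataFrame(
        {
            "person_id": [1, 2, 2, 3, 4, 5, 5],
            "wave": [3, 1, 3, 1, 1, 1, 3],
            "interview_date": pd.to_datetime(
                [
                    "2014-06-01",  # person 1: age 15 -> dropped
                    "2010-01-01",  # person 2: incomplete GHQ -> dropped
                    "2013-01-01",  # person 2: complete, retained
                    "2010-01-01",  # person 3: out-of-scope ethnicity
                    "2010-01-01",  # person 4: missing sex
                    "2021-01-01",  # person 5: out of window
                    "2013-06-01",  # person 5: retained
                ]
            ),
        }
    )
    for c in ITEM_COLUMNS:
        obs[c] = 1.0
    obs.loc[1, ITEM_COLUMNS[0]] = np.nan  # person 2 wave 1 incomplete
    return persons, obs


def test_filters_apply_stated_rules_in_order():
    persons, obs = _toy_cohort()
    rows, log = apply_eligibility_filters(persons, add_ghq_totals(obs))
    frame = log.to_frame().set_index("step")

    assert set(rows["person_id"]) == {2, 5}
    # person 2 keeps only the complete wave-3 interview
    assert rows.loc[rows["person_id"] == 2, "wave"].tolist() == [3]
    assert frame.loc["outside_period_windows", "records_removed"] == 1
    assert frame.loc["under_16_at_interview", "persons_removed"] == 1
    assert frame.loc["incomplete_ghq12_outcome", "records_removed"] == 1
    assert frame.loc["missing_sex_or_birth_year", "persons_removed"] == 1
    assert frame.loc["out_of_scope_ethnicity", "persons_removed"] == 1


def test_filter_accounting_partitions_the_input():
    persons, obs = _toy_cohort()
    _, log = apply_eligibility_filters(persons, add_ghq_totals(obs))
    frame = log.to_frame()
    assert (
        frame["persons_removed"].sum() + frame["persons_remaining"].iloc[-1]
        == persons["person_id"].nunique()
    )
    assert (
        frame["records_removed"].sum() + frame["records_remaining"].iloc[-1]
        == len(obs)
    )


def test_filters_are_idempotent():
    persons, obs = _toy_cohort()
    rows1, _ = apply_eligibility_filters(persons, add_ghq_totals(obs))
    rows2, log2 = apply_eligibility_filters(persons, rows1)
    assert len(rows2) == len(rows1)
    assert log2.to_frame()["records_removed"].sum() == 0
    pd.testing.assert_frame_equal(
        rows1.reset_index(drop=True)[rows2.columns], rows2.reset_index(drop=True)
    )


def test_rows_get_period_consistent_with_date():
    persons, obs = _toy_cohort()
    rows, _ = apply_eligibility_filters(persons, add_ghq_totals(obs))
    for _, r in rows.iterrows():
        assert assign_exposure_period(r["interview_date"].date()) == r["period"]
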