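"""Synthetic cohort generator: determinism, calibration, planted effects."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import ghqits as g
from ghqits.design import DEFAULT_PERIODS
from ghqits.ghq import ITEM_COLUMNS


def _noiseless(**overrides):
    base = dict(
        n_persons=400,
        baseline_ghq_mean=(10.0,) * 6,
        baseline_ghq_sd=(0.0,) * 6,
        true_level_effects=np.zeros((6, 2)),
        true_slope_effects=np.zeros((6, 3)),
        secular_trend=0.0,
        sigma_year=0.0,
        sigma_area=0.0,
        sigma_resid=0.0,
        covariate_missing_prob=0.0,
        seed=5,
    )
    base.update(overrides)
    return g.SimulationConfig(**base)


def test_degenerate_mixture_yields_single_ethnicity():
    cfg = g.SimulationConfig(
        n_persons=300, ethnic_proportions=(1, 0, 0, 0, 0, 0), seed=1
    )
    persons, _, _ = g.simulate_cohort(cfg)
    assert (persons["ethnicity"] == "White").all()


def test_seeded_determinism():
    cfg = g.SimulationConfig(n_persons=300, seed=9)
    p1, o1, t1 = g.simulate_cohort(cfg)
    p2, o2, t2 = g.simulate_cohort(cfg)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(o1, o2)
    assert t1 == t2


def test_noiseless_degenerate_scores_exactly_ten():
    _, obs, _ = g.simulate_cohort(_noiseless())
    totals = obs[ITEM_COLUMNS].sum(axis=1)
    assert (totals == 10).all()


def test_item_sum_equals_clamped_rounded_latent(small_cohort):
    _, obs, _, _ = small_cohort
    # fixture already has missingness in covariates, never in items
    totals = obs[ITEM_COLUMNS].to_numpy().sum(axis=1)
    expected = np.clip(np.rint(obs["ghq_total_latent"].to_numpy()), 0, 36)
    np.testing.assert_array_equal(totals, expected)


def test_planted_did_identity_in_noiseless_output():
    """With all noise off, the empirical difference-in-differences equals
    the planted level effect exactly."""
    level = np.zeros((6, 2))
    level[g.ETHNICITIES.index("Black Caribbean")] = (1.0, 2.0)
    cfg = _noiseless(n_persons=2000, true_level_effects=level)
    persons, obs, _ = g.simulate_cohort(cfg)
    rows, _ = g.apply_eligibility_filters(persons, g.add_ghq_totals(obs))
    cell = rows.groupby(["ethnicity", "period"])["ghq_total"].mean()
    did2 = (cell["Black Caribbean"][2] - cell["Black Caribbean"][1]) - (
        cell["White"][2] - cell["White"][1]
    )
    did3 = (cell["Black Caribbean"][3] - cell["Black Caribbean"][1]) - (
        cell["White"][3] - cell["White"][1]
    )
    assert did2 == pytest.approx(1.0, abs=1e-9)
    assert did3 == pytest.approx(2.0, abs=1e-9)


def test_group_means_calibrate_to_configured_baselines():
    """Pre-interruption latent means converge on the configured values."""
    cfg = g.SimulationConfig(n_persons=20_000, covariate_missing_prob=0.0, seed=2)
    _, obs, _ = g.simulate_cohort(cfg)
    persons, obs = _with_ethnicity(cfg, obs)
    pre = obs[obs["interview_date"] < pd.Timestamp(DEFAULT_PERIODS[1].start_date)]
    white = pre[pre["ethnicity"] == "White"]["ghq_total_latent"]
    mcse = white.std() / np.sqrt(len(white))
    assert abs(white.mean() - 11.1) < 4 * mcse


def _with_ethnicity(cfg, obs):
    persons, _, _ = g.simulate_cohort(cfg)
    return persons, obs.merge(persons[["person_id", "ethnicity"]], on="person_id")


def test_interview_dates_fall_inside_wave_windows(small_cohort):
    _, obs, _, cfg = small_cohort
    for wave, (start, end) in enumerate(cfg.wave_windows, start=1):
        d = obs.loc[obs["wave"] == wave, "interview_date"]
        assert (d >= pd.Timestamp(start)).all() and (d <= pd.Timestamp(end)).all()
    assert not obs.duplicated(["person_id", "wave"]).any()


def test_missingness_rate_and_identity():
    cfg = g.SimulationConfig(n_persons=1200, covariate_missing_prob=0.129, seed=3)
    _, obs, _ = g.simulate_cohort(cfg)
    masked = g.inject_missingness(obs, cfg)
    cells = masked[g.MASKABLE_COVARIATES]
    n_cells = cells.size
    frac = cells.isna().to_numpy().mean()
    se = np.sqrt(0.129 * 0.871 / n_cells)
    assert abs(frac - 0.129) < 3 * se

    cfg0 = dataclasses.replace(cfg, covariate_missing_prob=0.0)
    pd.testing.assert_frame_equal(g.inject_missingness(obs, cfg0), obs)


@pytest.mark.parametrize(
    "bad",
    [
        dict(covariate_missing_prob=1.0),
        dict(ethnic_proportions=(0.5, 0.5, 0.5, 0, 0, 0)),
        dict(sigma_resid=-1.0),
        dict(n_persons=0),
        dict(response_prob=np.zeros((8, 3))),
    ],
)
def test_config_violations_rejected_before_sampling(bad):
    with pytest.raises(ValueError):
        g.simulate_cohort(g.SimulationConfig(**bad))


def test_truth_map_records_planted_parameters(small_cohort):
    *_, truth, cfg = small_cohort
    assert truth["level_effect.Black Caribbean.period2"] == pytest.approx(0.67)
    assert truth["level_effect.Black Caribbean.period3"] == pytest.approx(1.28)
    assert truth["sigma_resid"] == cfg.sigma_resid
    assert 0 <= truth["clamp_fraction"] < 0.05


def test_cohort_csv_round_trip(tmp_path, small_cohort):
    persons, obs, truth, _ = small_cohort
    path = g.write_cohort(persons, obs, truth, tmp_path)
    p2, o2 = g.read_cohort(path)
    assert len(p2) == len(persons)
    assert len(o2) == len(obs)
    merged = o2.merge(p2[["person_id", "ethnicity"]], on="person_id")
    orig = obs.merge(persons[["person_id", "ethnicity"]], on="person_id")
    assert (merged["ethnicity"].to_numpy() == orig["ethnicity"].to_numpy()).all()
    np.testing.assert_allclose(
        o2[ITEM_COLUMNS].to_numpy(), obs[ITEM_COLUMNS].to_numpy()
    )
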