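"""Synthetic UKHLS-like longitudinal cohorts with known ground truth.

The real panel behind the analysis is licence-restricted, so every
downstream stage is exercised on cohorts drawn from a generator whose
data-generating process mirrors the fitted interrupted-time-series model:

    latent mean = group baseline
                + secular_trend * years-since-study-start
                + level effect(ethnicity, current period)
                + slope effect(ethnicity, period) * years-since-period-start
                + year random effect + area random effect

The observed GHQ-12 total is the latent mean plus Gaussian noise, rounded
and clamped to [0, 36], then decomposed into twelve item scores whose sum
equals the total.  Default calibration reproduces the published cohort's
ethnic composition, UK-born fractions and baseline GHQ-12 means, eleven
overlapping 24-month wave windows from Aug 2009, stratified non-response
across exposure periods, and ~13% item-level covariate missingness.

All randomness flows from ``SimulationConfig.seed``; identical configs
give byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DAYS_PER_YEAR, DEFAULT_PERIODS, ETHNICITIES
from .ghq import ITEM_COLUMNS

# ---------------------------------------------------------------------------
# covariate dictionaries (simple multinomials; see Non-goals in docs)
# ---------------------------------------------------------------------------

#: covariates that inject_missingness may mask.  GHQ items, sex and birth
#: year are never masked here: their absence is an eligibility concern.
MASKABLE_COVARIATES = [
    "urban",
    "relationship",
    "n_children",
    "education",
    "health_impairment",
    "housing",
    "imd_decile",
    "employment",
    "income_band",
    "uk_born",
]

COVARIATE_LEVELS: dict[str, list[int]] = {
    "urban": [0, 1],
    "relationship": [0, 1],
    "n_children": [0, 1, 2, 3],
    "education": [0, 1, 2, 3, 4, 5],  # postgrad..none
    "health_impairment": [0, 1],
    "housing": [0, 1, 2],  # owned, private rented, state rented
    "imd_decile": list(range(1, 11)),
    "employment": [0, 1, 2, 3, 4, 5],
    "income_band": [1, 2, 3, 4, 5, 6],  # 1 = lowest
    "uk_born": [0, 1],
}

# marginal level probabilities, loosely matched to the published cohort
DEFAULT_COVARIATE_PROBS: dict[str, tuple[float, ...]] = {
    "urban": (0.175, 0.825),
    "relationship": (0.253, 0.747),
    "n_children": (0.60, 0.20, 0.13, 0.07),
    "education": (0.106, 0.227, 0.216, 0.226, 0.093, 0.132),
    "health_impairment": (0.685, 0.315),
    "housing": (0.646, 0.186, 0.168),
    "imd_decile": (0.1,) * 10,
    "employment": (0.450, 0.076, 0.097, 0.198, 0.064, 0.115),
    "income_band": (0.192, 0.312, 0.179, 0.118, 0.086, 0.113),
}

#: median age at the 2014 Immigration Act, per ethnic group
DEFAULT_AGE_MEDIANS = (47.0, 35.0, 43.0, 38.0, 33.0, 32.0)

ACT_DATE = date(2014, 5, 14)


def default_wave_windows(n_waves: int = 11) -> list[tuple[date, date]]:
    """Eleven 24-month interview windows, each starting 12 months after
    the previous, so adjacent waves overlap by a year (as in UKHLS)."""
    windows = []
    for k in range(n_waves):
        start_month = 8 + 12 * k  # months since Jan 2009
        sy, sm = 2009 + (start_month - 1) // 12, (start_month - 1) % 12 + 1
        start = date(sy, sm, 1)
        end = (pd.Timestamp(date(sy + 2, sm, 1)) - pd.Timedelta(days=1)).date()
        windows.append((start, end))
    return windows


def _default_response_prob() -> np.ndarray:
    base = np.linspace(0.70, 0.90, 8)
    period_mult = np.array([1.0, 0.90, 0.85])
    return np.clip(base[:, None] * period_mult[None, :], 0.05, 0.95)


def _default_level_effects() -> np.ndarray:
    # rows = ethnicities, cols = (period 2, period 3); GHQ points vs White
    # and vs period 1.  Black Caribbean carries the planted policy effect.
    eff = np.zeros((6, 2))
    eff[ETHNICITIES.index("Black Caribbean")] = (0.67, 1.28)
    return eff


@dataclass
class SimulationConfig:
    """Parameters of the synthetic data-generating process.

    Defaults reproduce the published cohort's composition and baseline
    distress levels and plant the headline Black Caribbean level effects
    (+0.67 GHQ points in period 2, +1.28 in period 3, relative to White
    and to period 1); slope effects and the secular trend default to 0.
    """

    n_persons: int = 2000
    ethnic_proportions: tuple[float, ...] = (
        0.7890,
        0.0434,
        0.0378,
        0.0543,
        0.0482,
        0.0273,
    )
    baseline_ghq_mean: tuple[float, ...] = (11.1, 10.3, 11.4, 10.9, 11.9, 11.7)
    baseline_ghq_sd: tuple[float, ...] = (5.4, 5.8, 6.0, 5.8, 6.3, 6.0)
    uk_born_prob: tuple[float, ...] = (0.90, 0.21, 0.62, 0.37, 0.45, 0.44)
    age_median: tuple[float, ...] = DEFAULT_AGE_MEDIANS
    n_strata: int = 8
    n_areas: int = 30
    wave_windows: list[tuple[date, date]] = field(default_factory=default_wave_windows)
    response_prob: np.ndarray = field(default_factory=_default_response_prob)
    covariate_missing_prob: float = 0.13
    true_level_effects: np.ndarray = field(default_factory=_default_level_effects)
    true_slope_effects: np.ndarray = field(default_factory=lambda: np.zeros((6, 3)))
    secular_trend: float = 0.0
    sigma_year: float = 0.3
    sigma_area: float = 0.5
    sigma_resid: float = 5.4
    heteroscedastic: bool = False  # noise SD = per-group baseline SD instead
    covariate_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PROBS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        props = np.asarray(self.ethnic_proportions, dtype=float)
        if props.shape != (6,) or (props < 0).any():
            raise ValueError("ethnic_proportions must be 6 nonnegative values")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("ethnic_proportions must sum to 1 within 1e-9")
        for name in ("baseline_ghq_sd",):
            if (np.asarray(getattr(self, name)) < 0).any():
                raise ValueError(f"{name} must be nonnegative")
        for name in ("sigma_year", "sigma_area", "sigma_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        rp = np.asarray(self.response_prob, dtype=float)
        if rp.shape != (self.n_strata, 3):
            raise ValueError("response_prob must have shape (n_strata, 3)")
        if (rp <= 0).any() or (rp > 1).any():
            raise ValueError("response probabilities must lie in (0, 1]")
        if not 0 <= self.covariate_missing_prob < 1:
            raise ValueError("covariate_missing_prob must lie in [0, 1)")
        if np.asarray(self.true_level_effects).shape != (6, 2):
            raise ValueError("true_level_effects must have shape (6, 2)")
        if np.asarray(self.true_slope_effects).shape != (6, 3):
            raise ValueError("true_slope_effects must have shape (6, 3)")
        windows = [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.wave_windows]
        for (a, b) in windows:
            if b < a:
                raise ValueError("wave window ends before it starts")
        for (a1, _), (a2, _) in zip(windows, windows[1:]):
            if a2 < a1:
                raise ValueError("wave windows must be chronologically ordered")

    # -- YAML round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wave_windows"] = [[str(a), str(b)] for a, b in self.wave_windows]
        d["response_prob"] = np.asarray(self.response_prob).tolist()
        d["true_level_effects"] = np.asarray(self.true_level_effects).tolist()
        d["true_slope_effects"] = np.asarray(self.true_slope_effects).tolist()
        d["covariate_probs"] = {k: list(v) for k, v in self.covariate_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "wave_windows" in d:
            d["wave_windows"] = [
                (pd.Timestamp(a).date(), pd.Timestamp(b).date())
                for a, b in d["wave_windows"]
            ]
        for key in ("response_prob", "true_level_effects", "true_slope_effects"):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        for key in (
            "ethnic_proportions",
            "baseline_ghq_mean",
            "baseline_ghq_sd",
            "uk_born_prob",
            "age_median",
        ):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _split_items(totals: np.ndarray) -> np.ndarray:
    """Greedy decomposition of 0–36 totals into 12 items in {0..3}:
    item j takes min(3, remaining)."""
    offsets = 3 * np.arange(12)
    return np.clip(totals[:, None] - offsets[None, :], 0, 3).astype(np.int8)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw a cohort: person table, observation table, and the truth map.

    Persons carry fixed attributes; observations are one row per
    responding person-wave with interview date, GHQ items, the unclamped
    latent total (``ghq_total_latent``) and covariate copies.  The truth
    map records every planted parameter plus the realised clamp fraction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    eth_idx = rng.choice(6, size=n, p=np.asarray(config.ethnic_proportions))
    stratum = rng.integers(1, config.n_strata + 1, size=n)
    area = rng.integers(1, config.n_areas + 1, size=n)
    sex = rng.integers(0, 2, size=n)  # 1 = female
    age_at_act = np.clip(
        rng.normal(np.asarray(config.age_median)[eth_idx], 18.0), 12, 95
    )
    birth_year = ACT_DATE.year - np.round(age_at_act).astype(int)
    uk_born = (
        rng.random(n) < np.asarray(config.uk_born_prob)[eth_idx]
    ).astype(int)

    persons = pd.DataFrame(
        {
            "person_id": np.arange(1, n + 1),
            "ethnicity": np.asarray(ETHNICITIES, dtype=object)[eth_idx],
            "stratum": stratum,
            "area": area,
            "sex": sex,
            "birth_year": birth_year,
            "uk_born": uk_born,
        }
    )
    for cov in MASKABLE_COVARIATES:
        if cov == "uk_born":
            continue
        levels = np.asarray(COVARIATE_LEVELS[cov])
        probs = np.asarray(config.covariate_probs[cov], dtype=float)
        persons[cov] = rng.choice(levels, size=n, p=probs / probs.sum())

    # random effects: one level per calendar year spanned by the windows,
    # one per area; iid Gaussian
    first_year = min(pd.Timestamp(a).year for a, _ in config.wave_windows)
    last_year = max(pd.Timestamp(b).year for _, b in config.wave_windows)
    years = np.arange(first_year, last_year + 1)
    u_year = rng.normal(0.0, config.sigma_year, size=len(years))
    v_area = rng.normal(0.0, config.sigma_area, size=config.n_areas)

    level = np.asarray(config.true_level_effects, dtype=float)
    slope = np.asarray(config.true_slope_effects, dtype=float)
    base_mean = np.asarray(config.baseline_ghq_mean, dtype=float)
    base_sd = np.asarray(config.baseline_ghq_sd, dtype=float)

    origin = np.datetime64(DEFAULT_PERIODS[0].start_date)
    p2_start = np.datetime64(DEFAULT_PERIODS[1].start_date)
    p3_start = np.datetime64(DEFAULT_PERIODS[2].start_date)
    period_starts = [np.datetime64(p.start_date) for p in DEFAULT_PERIODS]

    frames: list[pd.DataFrame] = []
    n_clamped = 0
    n_total_obs = 0
    for wave, (wstart, wend) in enumerate(config.wave_windows, start=1):
        ws = np.datetime64(wstart)
        span = int((np.datetime64(wend) - ws).astype("timedelta64[D]").astype(int)) + 1
        dates = ws + rng.integers(0, span, size=n).astype("timedelta64[D]")
        # generation-side period: period 3 extends past the study end so
        # late interviews still get coherent outcomes (filters drop them)
        period = np.where(
            dates < p2_start, 1, np.where(dates < p3_start, 2, 3)
        )
        p_resp = np.asarray(config.response_prob)[stratum - 1, period - 1]
        responds = rng.random(n) < p_resp

        idx = np.nonzero(responds)[0]
        if idx.size == 0:
            continue
        d = dates[idx]
        e = eth_idx[idx]
        p = period[idx]
        t = (d - origin).astype("timedelta64[D]").astype(float) / DAYS_PER_YEAR
        pstart = np.array(period_starts, dtype="datetime64[D]")[p - 1]
        tsp = (d - pstart).astype("timedelta64[D]").astype(float) / DAYS_PER_YEAR

        lvl = np.where(p == 1, 0.0, level[e, np.clip(p - 2, 0, 1)])
        slp = slope[e, p - 1]
        yr = d.astype("datetime64[Y]").astype(int) + 1970
        latent = (
            base_mean[e]
            + config.secular_trend * t
            + lvl
            + slp * tsp
            + u_year[yr - first_year]
            + v_area[area[idx] - 1]
        )
        noise_sd = base_sd[e] if config.heteroscedastic else config.sigma_resid
        latent_obs = latent + rng.normal(0.0, 1.0, size=idx.size) * noise_sd
        total = np.rint(latent_obs)
        n_clamped += int(((total < 0) | (total > 36)).sum())
        n_total_obs += idx.size
        total = np.clip(total, 0, 36).astype(int)

        frame = pd.DataFrame(
            {
                "person_id": idx + 1,
                "wave": wave,
                "interview_date": pd.to_datetime(d),
                "ghq_total_latent": latent_obs,
            }
        )
        items = _split_items(total)
        for j, col in enumerate(ITEM_COLUMNS):
            frame[col] = items[:, j]
        frames.append(frame)

    observations = pd.concat(frames, ignore_index=True)
    observations = observations.sort_values(
        ["person_id", "wave"], kind="mergesort"
    ).reset_index(drop=True)
    # covariate copies travel on the observation rows (time-varying slots)
    cov_cols = ["person_id"] + MASKABLE_COVARIATES
    observations = observations.merge(persons[cov_cols], on="person_id", how="left")
    observations[MASKABLE_COVARIATES] = observations[MASKABLE_COVARIATES].astype(float)

    truth: dict[str, float] = {
        "seed": config.seed,
        "n_persons": n,
        "secular_trend": config.secular_trend,
        "sigma_year": config.sigma_year,
        "sigma_area": config.sigma_area,
        "sigma_resid": config.sigma_resid,
        "clamp_fraction": n_clamped / max(n_total_obs, 1),
    }
    for g, eth in enumerate(ETHNICITIES):
        truth[f"baseline_mean.{eth}"] = float(base_mean[g])
        truth[f"baseline_sd.{eth}"] = float(base_sd[g])
        truth[f"level_effect.{eth}.period2"] = float(level[g, 0])
        truth[f"level_effect.{eth}.period3"] = float(level[g, 1])
        for pp in (1, 2, 3):
            truth[f"slope_effect.{eth}.period{pp}"] = float(slope[g, pp - 1])
    for y, uy in zip(years, u_year):
        truth[f"year_effect.{y}"] = float(uy)
    for k, vk in enumerate(v_area, start=1):
        truth[f"area_effect.{k}"] = float(vk)

    return persons, observations, truth


def inject_missingness(
    observations: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mask maskable covariate cells independently with the configured
    probability.  GHQ items, sex and birth year are never masked here."""
    config.validate()
    prob = config.covariate_missing_prob
    out = observations.copy()
    if prob == 0:
        return out
    if rng is None:
        rng = np.random.default_rng([config.seed, 7919])
    cols = [c for c in MASKABLE_COVARIATES if c in out.columns]
    mask = rng.random((len(out), len(cols))) < prob
    vals = out[cols].to_numpy(dtype=float)
    vals[mask] = np.nan
    out[cols] = vals
    return out


# ---------------------------------------------------------------------------
# persistence: long-format CSV + YAML truth sidecar
# ---------------------------------------------------------------------------


def write_cohort(
    persons: pd.DataFrame,
    observations: pd.DataFrame,
    truth: dict,
    outdir: str | Path,
) -> Path:
    """Write ``cohort.csv`` (one row per person-interview, person
    attributes merged on, missing cells empty) and ``truth.yaml``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    person_cols = [
        c for c in persons.columns if c not in observations.columns or c == "person_id"
    ]
    long = observations.merge(persons[person_cols], on="person_id", how="left")
    long.to_csv(outdir / "cohort.csv", index=False)
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return outdir / "cohort.csv"


def read_cohort(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format cohort CSV back into person/observation tables."""
    long = pd.read_csv(path, parse_dates=["interview_date"])
    person_cols = ["person_id", "ethnicity", "stratum", "area", "sex", "birth_year"]
    persons = (
        long[person_cols + [c for c in MASKABLE_COVARIATES if c in long.columns]]
        .groupby("person_id", as_index=False)
        .first()
    )
    obs_cols = [
        c
        for c in long.columns
        if c not in ("ethnicity", "stratum", "area", "sex", "birth_year")
    ]
    observations = long[obs_cols].copy()
    return persons, observations
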