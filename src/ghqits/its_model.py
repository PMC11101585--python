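"""Bayesian interrupted-time-series linear model for GHQ-12 distress.

The linear predictor contains main effects for ethnic group and exposure
period, all confounders, a linear calendar-time trend (years), a linear
"time since the start of the current exposure period" term, interactions
of ethnicity with period (the level changes, i.e. the mean differences of
interest) and with time-since-period (the slope changes), plus iid
Gaussian random effects for calendar year (residual temporal confounding)
and local-authority area (residual spatial confounding).

Likelihood and priors
---------------------
Each analysis row has an inverse-probability-of-response weight w_i that
enters the Gaussian likelihood as a precision multiplier,

    y_i ~ Normal(x_i'beta + u_year(i) + v_area(i),  sigma^2 / w_i),

the standard Bayesian analogue of weighted least squares (for location
parameters this coincides with multiplying each row's log-likelihood
contribution by w_i, and a globally rescaled weight vector cancels from
the coefficient posterior).  Coefficients get weakly informative
Normal(0, scale^2) priors (scale 10 GHQ points by default; ``None``
means flat), and the three standard deviations (residual, year, area)
get half-Normal(0, 5^2) priors.

Inference is by a blocked Gibbs sampler written here: the coefficient
vector and each random-effect block have conjugate Gaussian conditionals;
the standard deviations are updated by univariate slice sampling on the
log scale.  Posterior means of coefficients and random effects are
Rao-Blackwellised (averages of their conditional Gaussian means), so
with a flat prior and no random effects the reported posterior mean is
the weighted-least-squares solution exactly, not just up to Monte-Carlo
error.  Convergence is checked with rank-normalised split R-hat and
effective sample size; a non-converged run is flagged, never silently
returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .design import ETHNICITIES

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6

#: default confounder set (the twelve adjustment variables)
DEFAULT_CONFOUNDERS = [
    "sex",
    "age",
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

#: confounders entered as continuous (everything else is categorical)
CONTINUOUS_CONFOUNDERS = {"age"}


@dataclass
class ITSModelSpec:
    """Coefficient layout, priors and inference configuration."""

    reference_ethnicity: str = "White"
    period_coding: str = "vs-baseline"  # or "sequential"
    slope_interactions: str = "shared"  # or "by-period"
    confounders: list[str] = field(default_factory=lambda: list(DEFAULT_CONFOUNDERS))
    include_calendar_time: bool = True
    random_effects: tuple[str, ...] = ("year", "area")
    person_intercept: bool = False
    coef_prior_scale: float | None = 10.0  # GHQ points; None = flat
    sd_prior_scale: float = 5.0  # half-Normal scale for all SDs
    draws: int = 500
    warmup: int = 250
    chains: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.period_coding not in ("vs-baseline", "sequential"):
            raise ValueError("period_coding must be 'vs-baseline' or 'sequential'")
        if self.slope_interactions not in ("shared", "by-period"):
            raise ValueError("slope_interactions must be 'shared' or 'by-period'")
        if self.coef_prior_scale is not None and self.coef_prior_scale <= 0:
            raise ValueError("coef_prior_scale must be positive or None")
        if self.sd_prior_scale <= 0:
            raise ValueError("sd_prior_scale must be positive")
        for re in self.random_effects:
            if re not in ("year", "area"):
                raise ValueError(f"unknown random effect {re!r}")


@dataclass
class DesignMatrices:
    y: np.ndarray
    w: np.ndarray
    X: np.ndarray
    columns: list[str]
    year_idx: np.ndarray | None
    area_idx: np.ndarray | None
    person_idx: np.ndarray | None
    year_levels: np.ndarray | None
    area_levels: np.ndarray | None
    person_levels: np.ndarray | None


def _period_columns(period: np.ndarray, coding: str) -> dict[str, np.ndarray]:
    if coding == "vs-baseline":
        return {
            "period[2]": (period == 2).astype(float),
            "period[3]": (period == 3).astype(float),
        }
    # sequential: period-3 contrast is the increment over period 2
    return {
        "period[2]": (period >= 2).astype(float),
        "period[3]": (period == 3).astype(float),
    }


def build_design_matrix(pooled: pd.DataFrame, spec: ITSModelSpec) -> DesignMatrices:
    """Build outcome, weight and fixed-effect matrices plus RE indices.

    Dummy coding with the stated reference levels; interaction columns
    are elementwise products of their parents; column order (and hence
    naming) is deterministic.  Constant columns are dropped with a
    logged warning; rank deficiency is reported.
    """
    spec.validate()
    confounder_cells = [
        c for c in spec.confounders if c in pooled.columns
    ]
    needed = confounder_cells + ["ghq_total", "ethnicity", "period"]
    for c in needed:
        if pooled[c].isna().any():
            raise ValueError(f"column {c!r} still has missing cells")

    y = pooled["ghq_total"].to_numpy(dtype=float)
    w = (
        pooled["weight"].to_numpy(dtype=float)
        if "weight" in pooled.columns
        else np.ones(len(pooled))
    )

    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(pooled))}

    eth = pooled["ethnicity"].to_numpy()
    eth_names = [
        e for e in ETHNICITIES if e != spec.reference_ethnicity and (eth == e).any()
    ]
    for e in eth_names:
        cols[f"eth[{e}]"] = (eth == e).astype(float)

    period = pooled["period"].to_numpy(dtype=int)
    pcols = _period_columns(period, spec.period_coding)
    cols.update(pcols)

    for e in eth_names:
        for pname, pcol in pcols.items():
            cols[f"eth[{e}]:{pname}"] = cols[f"eth[{e}]"] * pcol

    if spec.include_calendar_time:
        cols["calendar_time"] = pooled["calendar_time"].to_numpy(dtype=float)

    tsp = pooled["time_since_period"].to_numpy(dtype=float)
    if spec.slope_interactions == "shared":
        cols["time_since_period"] = tsp
        for e in eth_names:
            cols[f"eth[{e}]:time_since_period"] = cols[f"eth[{e}]"] * tsp
    else:
        for p in (1, 2, 3):
            cols[f"time_since_period[{p}]"] = tsp * (period == p)
        for e in eth_names:
            for p in (2, 3):
                cols[f"eth[{e}]:time_since_period[{p}]"] = (
                    cols[f"eth[{e}]"] * tsp * (period == p)
                )

    for c in confounder_cells:
        if c in CONTINUOUS_CONFOUNDERS:
            v = pooled[c].to_numpy(dtype=float)
            cols[c] = v - v.mean()  # centred so the intercept stays interpretable
        else:
            v = pooled[c].astype(float).astype(int).to_numpy()
            levels = np.sort(np.unique(v))
            for lev in levels[1:]:  # lowest level is the reference
                cols[f"{c}[{lev}]"] = (v == lev).astype(float)

    names, arrays = [], []
    for name, arr in cols.items():
        if name != "Intercept" and np.ptp(arr) == 0:
            logger.warning("dropping constant design column %r", name)
            continue
        names.append(name)
        arrays.append(arr)
    X = np.column_stack(arrays)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "design matrix is rank deficient: rank %d < %d columns", rank, X.shape[1]
        )

    def _index(colname: str):
        vals = pooled[colname].to_numpy()
        levels, idx = np.unique(vals, return_inverse=True)
        return idx.astype(np.int64), levels

    year_idx = area_idx = person_idx = None
    year_levels = area_levels = person_levels = None
    if "year" in spec.random_effects:
        yrs = pd.to_datetime(pooled["interview_date"]).dt.year.to_numpy()
        year_levels, year_idx = np.unique(yrs, return_inverse=True)
    if "area" in spec.random_effects:
        area_idx, area_levels = _index("area")
    if spec.person_intercept:
        person_idx, person_levels = _index("person_id")

    return DesignMatrices(
        y=y,
        w=w,
        X=X,
        columns=names,
        year_idx=year_idx,
        area_idx=area_idx,
        person_idx=person_idx,
        year_levels=year_levels,
        area_levels=area_levels,
        person_levels=person_levels,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _slice_sample_log_sd(
    x0: float,
    logpost,
    rng: np.random.Generator,
    width: float = 0.5,
    max_steps: int = 50,
    lower: float = np.log(SIGMA_FLOOR),
    upper: float = np.log(1e3),
) -> float:
    """One stepping-out slice-sampling update on a log-SD parameter."""
    f0 = logpost(x0)
    logy = f0 + np.log(rng.random() + 1e-300)
    u = rng.random()
    left, right = x0 - width * u, x0 + width * (1 - u)
    for _ in range(max_steps):
        if left <= lower or logpost(left) < logy:
            break
        left -= width
    for _ in range(max_steps):
        if right >= upper or logpost(right) < logy:
            break
        right += width
    left, right = max(left, lower), min(right, upper)
    for _ in range(100):
        x1 = left + rng.random() * (right - left)
        if logpost(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # degenerate slice; keep the current value


class _AdaptiveWidths:
    """Per-parameter slice widths, tuned during warmup and then frozen.

    A slice sampler is valid for any fixed width; tuning it to a few
    posterior SDs just minimises the number of density evaluations.
    """

    def __init__(self, names, init: float = 0.5):
        self.w = {k: init for k in names}
        self.frozen = False

    def update(self, name: str, step: float) -> None:
        if not self.frozen:
            target = max(6.0 * abs(step), 1e-3)
            self.w[name] = min(max(0.9 * self.w[name] + 0.1 * target, 1e-3), 2.0)


@dataclass
class PosteriorSummary:
    """Posterior summaries per parameter plus sampler diagnostics."""

    table: pd.DataFrame  # index: parameter; mean, sd, q2.5, q50, q97.5, rhat, ess
    converged: bool
    n_chains: int
    n_draws: int
    column_names: list[str]
    draws: dict | None = None  # parameter -> (chains, draws[, dim]) arrays

    def coefficient(self, name: str) -> pd.Series:
        if name not in self.table.index:
            raise KeyError(f"posterior has no coefficient named {name!r}")
        return self.table.loc[name]

    def draws_frame(self) -> pd.DataFrame:
        """Raw draws in long columnar form (one column per parameter)."""
        if self.draws is None:
            raise ValueError("draws were not retained for this fit")
        cols = {}
        for j, name in enumerate(self.column_names):
            cols[name] = self.draws["beta"][:, :, j].ravel()
        for key, arr in self.draws.items():
            if key != "beta":
                cols[key] = np.asarray(arr).reshape(-1)
        return pd.DataFrame(cols)


class _Suffstats:
    """Weighted cross-products shared by all chains.

    The coefficient vector and the year/area random effects are drawn as
    one joint Gaussian block, so their full conditional needs only these
    fixed cross-products; the per-iteration cost is independent of the
    number of rows.  An optional person-level intercept falls back to an
    O(n)-per-iteration conditional block.
    """

    def __init__(self, dm: DesignMatrices):
        y, w, X = dm.y, dm.w, dm.X
        self.n, self.p = X.shape
        Xw = X * w[:, None]
        self.yWy = float(w @ (y * y))

        self.block_names: list[str] = []
        self.block_sizes: list[int] = []
        idxs = []
        if dm.year_idx is not None:
            self.block_names.append("year")
            self.block_sizes.append(len(dm.year_levels))
            idxs.append(dm.year_idx)
        if dm.area_idx is not None:
            self.block_names.append("area")
            self.block_sizes.append(len(dm.area_levels))
            idxs.append(dm.area_idx)
        self.idxs = idxs

        q = self.p + sum(self.block_sizes)
        self.q = q
        Mlik = np.zeros((q, q))
        rhs = np.zeros(q)
        Mlik[: self.p, : self.p] = X.T @ Xw
        rhs[: self.p] = Xw.T @ y
        offs = [self.p]
        for L in self.block_sizes:
            offs.append(offs[-1] + L)
        self.offsets = offs
        for bi, (idx, L) in enumerate(zip(idxs, self.block_sizes)):
            o = offs[bi]
            C = np.zeros((L, self.p))
            np.add.at(C, idx, Xw)
            Mlik[o : o + L, : self.p] = C
            Mlik[: self.p, o : o + L] = C.T
            sw = np.bincount(idx, weights=w, minlength=L)
            Mlik[o : o + L, o : o + L] = np.diag(sw)
            rhs[o : o + L] = np.bincount(idx, weights=w * y, minlength=L)
        if len(idxs) == 2:
            J, K = self.block_sizes
            cross = np.zeros((J, K))
            np.add.at(cross, (idxs[0], idxs[1]), w)
            Mlik[offs[0] : offs[0] + J, offs[1] : offs[1] + K] = cross
            Mlik[offs[1] : offs[1] + K, offs[0] : offs[0] + J] = cross.T
        self.Mlik = Mlik
        self.rhs = rhs

        # optional person-intercept block (O(n) conditional updates)
        self.person = dm.person_idx is not None
        if self.person:
            self.y, self.w, self.X, self.Xw = y, w, X, Xw
            self.person_idx = dm.person_idx
            self.n_person = len(dm.person_levels)
            self.sw_person = np.bincount(
                dm.person_idx, weights=w, minlength=self.n_person
            )


def _run_chain(
    ss: _Suffstats,
    spec: ITSModelSpec,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """One chain of the collapsed blocked Gibbs sampler.

    The scale parameters (residual SD and each random-effect SD) are
    slice-sampled under the marginal posterior with every Gaussian
    parameter integrated out analytically, which removes the usual
    funnel between a variance component and its effects; the
    coefficient/random-effect vector is then drawn exactly from its
    joint Gaussian conditional.
    """
    p, q, n = ss.p, ss.q, ss.n
    prior_prec = 0.0 if spec.coef_prior_scale is None else spec.coef_prior_scale**-2
    c2 = spec.sd_prior_scale**2
    jitter = 1e-9 * float(np.diag(ss.Mlik)[:p].max()) + 1e-12

    taus = {name: 1.0 for name in ss.block_names}
    if ss.person:
        taus["person"] = 1.0
        pe = np.zeros(ss.n_person)
    sigma = 1.0
    widths = _AdaptiveWidths(["sigma", "person", *ss.block_names])
    P2buf = np.empty((q, q))
    diag_ix = np.diag_indices(q)

    def _prior_diag() -> np.ndarray:
        d = np.empty(q)
        d[:p] = prior_prec
        for name, L, o in zip(ss.block_names, ss.block_sizes, ss.offsets):
            d[o : o + L] = taus[name] ** -2
        return d

    n_keep = spec.draws
    out = {
        "beta": np.empty((n_keep, p)),
        "beta_cmean": np.empty((n_keep, p)),
        "sigma_resid": np.empty(n_keep),
    }
    for name, L in zip(ss.block_names, ss.block_sizes):
        out[f"sigma_{name}"] = np.empty(n_keep)
        out[f"u_{name}"] = np.empty((n_keep, L))
    if ss.person:
        out["sigma_person"] = np.empty(n_keep)

    for it in range(spec.warmup + n_keep):
        if it == spec.warmup:
            widths.frozen = True
        if ss.person:
            resid_pe = ss.y - pe[ss.person_idx]
            rhs = _project(ss, ss.w * resid_pe)
            yWy = float(ss.w @ (resid_pe * resid_pe))
        else:
            rhs, yWy = ss.rhs, ss.yWy

        def marginal_logpost(sig: float) -> float:
            """log p(sigma, taus | y) with the Gaussian block integrated
            out; evaluated at the current taus and the given sigma."""
            d = _prior_diag()
            np.copyto(P2buf, ss.Mlik)
            P2buf[diag_ix] += sig**2 * d + jitter
            try:
                cf = cho_factor(P2buf, lower=True, overwrite_a=True,
                                check_finite=False)
            except np.linalg.LinAlgError:
                return -np.inf
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            S = max(yWy - float(rhs @ cho_solve(cf, rhs, check_finite=False)), 0.0)
            lp = (
                -(n - q) * np.log(sig)
                - 0.5 * logdet
                - S / (2 * sig**2)
                - sig**2 / (2 * c2)
            )
            for name, L in zip(ss.block_names, ss.block_sizes):
                lp += -L * np.log(taus[name]) - taus[name] ** 2 / (2 * c2)
            return lp

        # --- scale parameters under the collapsed posterior ----------------
        x0 = np.log(sigma)
        x1 = _slice_sample_log_sd(
            x0, lambda x: marginal_logpost(np.exp(x)), rng, width=widths.w["sigma"]
        )
        widths.update("sigma", x1 - x0)
        sigma = max(np.exp(x1), SIGMA_FLOOR)
        for name in ss.block_names:

            def lp_tau(x, name=name):
                old = taus[name]
                taus[name] = np.exp(x)
                val = marginal_logpost(sigma)
                taus[name] = old
                return val

            x0 = np.log(taus[name])
            x1 = _slice_sample_log_sd(x0, lp_tau, rng, width=widths.w[name])
            widths.update(name, x1 - x0)
            taus[name] = np.exp(x1)

        # --- exact joint Gaussian draw: coefficients + year/area effects ---
        d = _prior_diag()
        np.copyto(P2buf, ss.Mlik)
        P2buf[diag_ix] += sigma**2 * d + jitter
        cf = cho_factor(P2buf, lower=True, overwrite_a=True, check_finite=False)
        mean_theta = cho_solve(cf, rhs, check_finite=False)
        z = rng.standard_normal(q)
        theta = mean_theta + sigma * solve_triangular(
            cf[0], z, lower=True, trans="T", check_finite=False
        )

        # --- optional person intercepts (O(n) conditional block) ------------
        if ss.person:
            fitted = ss.X @ theta[:p]
            for idx, o, L in zip(ss.idxs, ss.offsets, ss.block_sizes):
                fitted += theta[o : o + L][idx]
            r = ss.y - fitted
            s = np.bincount(ss.person_idx, weights=ss.w * r, minlength=ss.n_person)
            prec_pe = ss.sw_person / sigma**2 + taus["person"] ** -2
            pe = (s / sigma**2) / prec_pe + rng.standard_normal(
                ss.n_person
            ) / np.sqrt(prec_pe)
            ssq = float(pe @ pe)

            def lp_pe(x, ssq=ssq):
                t2 = np.exp(2 * x)
                return -ss.n_person * x - ssq / (2 * t2) - t2 / (2 * c2)

            x0 = np.log(taus["person"])
            x1 = _slice_sample_log_sd(x0, lp_pe, rng, width=widths.w["person"])
            widths.update("person", x1 - x0)
            taus["person"] = np.exp(x1)

        if it >= spec.warmup:
            k = it - spec.warmup
            out["beta"][k] = theta[:p]
            out["beta_cmean"][k] = mean_theta[:p]
            out["sigma_resid"][k] = sigma
            for name, L, o in zip(ss.block_names, ss.block_sizes, ss.offsets):
                out[f"sigma_{name}"][k] = taus[name]
                out[f"u_{name}"][k] = theta[o : o + L]
            if ss.person:
                out["sigma_person"][k] = taus["person"]
    return out


def _project(ss: _Suffstats, wvec: np.ndarray) -> np.ndarray:
    """Project an n-vector of weighted values onto the joint-block basis."""
    out = np.empty(ss.q)
    out[: ss.p] = ss.X.T @ wvec
    for idx, o, L in zip(ss.idxs, ss.offsets, ss.block_sizes):
        out[o : o + L] = np.bincount(idx, weights=wvec, minlength=L)
    return out


def fit_bayes_its(dm: DesignMatrices, spec: ITSModelSpec) -> PosteriorSummary:
    """Run the Gibbs sampler and summarise the posterior.

    Returns posterior mean (Rao-Blackwellised for coefficients), SD and
    central 95% interval per parameter, with split-R-hat and bulk ESS
    diagnostics.  A run failing the convergence checks is flagged via
    ``converged=False`` and a warning.
    """
    spec.validate()
    if (dm.w < 1 - 1e-9).any() and not np.allclose(dm.w, dm.w[0]):
        raise ValueError("weights must be >= 1 or all equal")
    ss = _Suffstats(dm)
    if ss.person:
        # the O(n) person block needs the raw arrays regardless
        ss.y, ss.w, ss.X = dm.y, dm.w, dm.X
    chains = [
        _run_chain(ss, spec, np.random.default_rng([spec.seed, 50021, c]))
        for c in range(spec.chains)
    ]

    p = dm.X.shape[1]
    beta_draws = np.stack([c["beta"] for c in chains])  # (C, D, p)
    beta_cmean = np.stack([c["beta_cmean"] for c in chains])
    records = {}
    for j, name in enumerate(dm.columns):
        d = beta_draws[:, :, j].ravel()
        records[name] = {
            "mean": beta_cmean[:, :, j].mean(),
            "sd": d.std(ddof=1),
            "q2.5": np.quantile(d, 0.025),
            "q50": np.quantile(d, 0.5),
            "q97.5": np.quantile(d, 0.975),
        }
    sd_params = [k for k in chains[0] if k.startswith("sigma_")]
    for name in sd_params:
        d = np.stack([c[name] for c in chains]).ravel()
        records[name] = {
            "mean": d.mean(),
            "sd": d.std(ddof=1),
            "q2.5": np.quantile(d, 0.025),
            "q50": np.quantile(d, 0.5),
            "q97.5": np.quantile(d, 0.975),
        }

    # diagnostics on the raw (non-Rao-Blackwellised) draws
    try:
        import arviz as az

        ds = {"beta": beta_draws}
        for name in sd_params:
            ds[name] = np.stack([c[name] for c in chains])
        idata = az.from_dict(posterior=ds)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        rhats = np.concatenate(
            [np.atleast_1d(np.asarray(rhat[v])).ravel() for v in ds]
        )
        esses = np.concatenate(
            [np.atleast_1d(np.asarray(ess[v])).ravel() for v in ds]
        )
        for j, name in enumerate(dm.columns):
            records[name]["rhat"] = float(np.asarray(rhat["beta"])[j])
            records[name]["ess"] = float(np.asarray(ess["beta"])[j])
        for name in sd_params:
            records[name]["rhat"] = float(np.asarray(rhat[name]))
            records[name]["ess"] = float(np.asarray(ess[name]))
        max_rhat = np.nanmax(rhats)
        min_ess = np.nanmin(esses)
        converged = bool(max_rhat < 1.05 and min_ess > 100)
        if not converged:
            logger.warning(
                "sampler not converged: max R-hat %.3f, min ESS %.0f",
                max_rhat,
                min_ess,
            )
    except Exception as exc:  # diagnostics must never crash a fit
        logger.warning("convergence diagnostics unavailable: %s", exc)
        converged = False

    table = pd.DataFrame.from_dict(records, orient="index")
    draws = {"beta": beta_draws}
    for name in sd_params:
        draws[name] = np.stack([c[name] for c in chains])
    return PosteriorSummary(
        table=table,
        converged=converged,
        n_chains=spec.chains,
        n_draws=spec.draws,
        column_names=list(dm.columns),
        draws=draws,
    )


# ---------------------------------------------------------------------------
# effect tables
# ---------------------------------------------------------------------------


def summarize_effects(posterior: PosteriorSummary, spec: ITSModelSpec) -> pd.DataFrame:
    """Arrange interaction coefficients as a per-group effect table.

    Rows are the minoritised ethnic groups plus the reference rendered
    "Ref"; columns give the period-2 and period-3 mean differences and
    the per-year slope contrasts, each with a 95% credible interval.
    With shared slope coding the single time-since-period contrast fills
    both period slope columns.
    """
    spec.validate()
    eth_names = [
        e
        for e in ETHNICITIES
        if e != spec.reference_ethnicity
        and f"eth[{e}]" in posterior.table.index
    ]
    rows = []
    for e in [spec.reference_ethnicity] + eth_names:
        rec: dict[str, object] = {"ethnicity": e}
        if e == spec.reference_ethnicity:
            rec["reference"] = True
            rows.append(rec)
            continue
        rec["reference"] = False
        for p in (2, 3):
            coef = posterior.coefficient(f"eth[{e}]:period[{p}]")
            rec[f"period{p}_md"] = coef["mean"]
            rec[f"period{p}_md_lo"] = coef["q2.5"]
            rec[f"period{p}_md_hi"] = coef["q97.5"]
            sname = (
                f"eth[{e}]:time_since_period"
                if spec.slope_interactions == "shared"
                else f"eth[{e}]:time_since_period[{p}]"
            )
            scoef = posterior.coefficient(sname)
            rec[f"period{p}_slope"] = scoef["mean"]
            rec[f"period{p}_slope_lo"] = scoef["q2.5"]
            rec[f"period{p}_slope_hi"] = scoef["q97.5"]
        rows.append(rec)
    return pd.DataFrame(rows).set_index("ethnicity")


def format_effect_table(effects: pd.DataFrame, digits: int = 2) -> pd.DataFrame:
    """Render an effect table as 'estimate (lo to hi)' strings, with the
    reference row shown as 'Ref'."""
    out = {}
    for p in (2, 3):
        for kind in ("md", "slope"):
            col = f"period{p}_{kind}"
            vals = []
            for e, row in effects.iterrows():
                if row.get("reference", False):
                    vals.append("Ref")
                else:
                    vals.append(
                        f"{row[col]:.{digits}f} "
                        f"({row[f'{col}_lo']:.{digits}f} to "
                        f"{row[f'{col}_hi']:.{digits}f})"
                    )
            out[col] = vals
    return pd.DataFrame(out, index=effects.index)
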