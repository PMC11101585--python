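"""Design-matrix layout, least-squares oracle equivalence, priors."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import ghqits as g
from ghqits.its_model import DesignMatrices, build_design_matrix, fit_bayes_its


def _pooled_frame(n=400, seed=0):
    """A small complete analysis table covering all six ethnic groups."""
    rng = np.random.default_rng(seed)
    eth = rng.choice(g.ETHNICITIES, size=n, p=[0.5, 0.1, 0.1, 0.1, 0.1, 0.1])
    period = rng.integers(1, 4, size=n)
    tsp = rng.random(n) * 3
    df = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "ethnicity": eth,
            "period": period,
            "calendar_time": rng.random(n) * 10,
            "time_since_period": tsp,
            "ghq_total": rng.integers(0, 37, size=n).astype(float),
            "weight": np.ones(n),
            "interview_date": pd.Timestamp("2015-06-01"),
            "area": rng.integers(1, 6, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age": rng.integers(16, 90, size=n).astype(float),
        }
    )
    return df


def _spec(**kw):
    kw.setdefault("confounders", ["sex", "age"])
    kw.setdefault("draws", 200)
    kw.setdefault("warmup", 100)
    return dataclasses.replace(g.ITSModelSpec(), **kw)


def test_design_matrix_column_census():
    """Six ethnicities and three periods give 5 ethnicity, 2 period,
    10 level-interaction, 1 time-since and 5 slope-interaction columns."""
    dm = build_design_matrix(_pooled_frame(), _spec(random_effects=()))
    names = dm.columns
    assert sum(n.startswith("eth[") and ":" not in n for n in names) == 5
    assert sum(n.startswith("period[") for n in names) == 2
    assert sum(":period[" in n for n in names) == 10
    assert names.count("time_since_period") == 1
    assert sum(n.endswith(":time_since_period") for n in names) == 5
    assert "calendar_time" in names


def test_reference_rows_code_to_zero():
    df = _pooled_frame()
    dm = build_design_matrix(df, _spec(random_effects=()))
    ref = (df["ethnicity"] == "White") & (df["period"] == 1)
    idx = ref.to_numpy().nonzero()[0][0]
    for j, name in enumerate(dm.columns):
        if name.startswith("eth[") or name.startswith("period["):
            assert dm.X[idx, j] == 0.0
    bc2 = ((df["ethnicity"] == "Black Caribbean") & (df["period"] == 2)).to_numpy()
    jdx = bc2.nonzero()[0][0]
    cols = {n: k for k, n in enumerate(dm.columns)}
    assert dm.X[jdx, cols["eth[Black Caribbean]"]] == 1.0
    assert dm.X[jdx, cols["period[2]"]] == 1.0
    assert dm.X[jdx, cols["eth[Black Caribbean]:period[2]"]] == 1.0


def test_interactions_are_products_of_parents():
    dm = build_design_matrix(_pooled_frame(), _spec(random_effects=()))
    cols = {n: k for k, n in enumerate(dm.columns)}
    for e in g.ETHNICITIES[1:]:
        for p in (2, 3):
            prod = dm.X[:, cols[f"eth[{e}]"]] * dm.X[:, cols[f"period[{p}]"]]
            np.testing.assert_array_equal(
                dm.X[:, cols[f"eth[{e}]:period[{p}]"]], prod
            )


def _random_dm(n=200, p=8, seed=1, weights=None):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    beta = rng.standard_normal(p)
    y = X @ beta + rng.standard_normal(n)
    w = np.ones(n) if weights is None else weights
    return DesignMatrices(
        y=y, w=w, X=X, columns=[f"x{j}" for j in range(p)],
        year_idx=None, area_idx=None, person_idx=None,
        year_levels=None, area_levels=None, person_levels=None,
    )


def test_flat_prior_posterior_mean_equals_least_squares():
    """Flat prior, unit weights, no random effects: the posterior mean
    must equal the normal-equations solution to 1e-6 relative."""
    dm = _random_dm()
    spec = _spec(coef_prior_scale=None, random_effects=())
    post = fit_bayes_its(dm, spec)
    oracle = np.linalg.solve(dm.X.T @ dm.X, dm.X.T @ dm.y)
    np.testing.assert_allclose(
        post.table["mean"].to_numpy()[: len(oracle)], oracle, rtol=1e-6, atol=1e-9
    )


def test_flat_prior_weighted_mean_equals_weighted_least_squares():
    rng = np.random.default_rng(7)
    w = 1.0 + 2.0 * rng.random(200)
    dm = _random_dm(weights=w)
    spec = _spec(coef_prior_scale=None, random_effects=())
    post = fit_bayes_its(dm, spec)
    Xw = dm.X * w[:, None]
    oracle = np.linalg.solve(dm.X.T @ Xw, Xw.T @ dm.y)
    np.testing.assert_allclose(
        post.table["mean"].to_numpy()[: len(oracle)], oracle, rtol=1e-6, atol=1e-9
    )


def test_globally_rescaled_weights_cancel():
    """Doubling every weight leaves coefficient posterior means unchanged
    under flat priors (weighted normal-equations algebra)."""
    dm1 = _random_dm(seed=3)
    dm2 = _random_dm(seed=3, weights=np.full(200, 2.0))
    spec = _spec(coef_prior_scale=None, random_effects=())
    m1 = fit_bayes_its(dm1, spec).table["mean"].to_numpy()[:8]
    m2 = fit_bayes_its(dm2, spec).table["mean"].to_numpy()[:8]
    np.testing.assert_allclose(m1, m2, rtol=1e-9)


def test_tightening_prior_shrinks_posterior_means_toward_zero():
    dm = _random_dm(seed=9)
    means = []
    for scale in (25.0, 1.0, 0.05):
        post = fit_bayes_its(dm, _spec(coef_prior_scale=scale, random_effects=()))
        means.append(np.abs(post.table["mean"].to_numpy()[1:8]).sum())
    assert means[0] > means[1] > means[2]


def test_quantile_ordering_invariant(main_result):
    table = main_result[0].posterior.table
    assert (table["q2.5"] <= table["q50"]).all()
    assert (table["q50"] <= table["q97.5"]).all()


def test_draws_frame_is_columnar_and_complete(main_result):
    post = main_result[0].posterior
    frame = post.draws_frame()
    assert len(frame) == post.n_chains * post.n_draws
    assert "sigma_resid" in frame.columns
    assert set(post.column_names) <= set(frame.columns)


def test_random_effect_sds_are_estimated(main_result):
    table = main_result[0].posterior.table
    for name in ("sigma_resid", "sigma_year", "sigma_area"):
        assert table.loc[name, "mean"] > 0


def _fake_posterior():
    rows = {
        "eth[Black Caribbean]": dict(mean=0.1, sd=0.1, **{"q2.5": 0, "q50": 0.1, "q97.5": 0.2}),
    }
    for p in (2, 3):
        rows[f"eth[Black Caribbean]:period[{p}]"] = dict(
            mean=0.67 if p == 2 else 1.28,
            sd=0.3,
            **{"q2.5": 0.06 if p == 2 else 0.34,
               "q50": 0.67 if p == 2 else 1.28,
               "q97.5": 1.28 if p == 2 else 2.21},
        )
    rows["eth[Black Caribbean]:time_since_period"] = dict(
        mean=0.05, sd=0.1, **{"q2.5": -0.1, "q50": 0.05, "q97.5": 0.2}
    )
    return g.PosteriorSummary(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        converged=True,
        n_chains=2,
        n_draws=100,
        column_names=list(rows),
    )


def test_effect_table_layout_and_reference_row():
    post = _fake_posterior()
    spec = _spec()
    effects = g.summarize_effects(post, spec)
    assert effects.loc["White", "reference"]
    bc = effects.loc["Black Caribbean"]
    assert bc["period2_md"] == pytest.approx(0.67)
    assert (bc["period2_md_lo"], bc["period2_md_hi"]) == (0.06, 1.28)
    assert bc["period3_md"] == pytest.approx(1.28)
    formatted = g.format_effect_table(effects)
    assert formatted.loc["White", "period2_md"] == "Ref"
    assert formatted.loc["Black Caribbean", "period2_md"] == "0.67 (0.06 to 1.28)"


def test_missing_coefficient_raises_by_name():
    post = _fake_posterior()
    post.table = post.table.drop(index="eth[Black Caribbean]:period[3]")
    with pytest.raises(KeyError, match="period\\[3\\]"):
        g.summarize_effects(post, _spec())
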