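"""Chained-equations imputation of categorical covariates, mode-pooled.

Missing covariate cells (all imputable covariates are categorical) are
filled by multiple imputation by chained equations: each incomplete
variable is regressed on all other covariates with a ridge-stabilised
multinomial logistic model, and its missing cells are redrawn from the
fitted conditional; the sweep repeats for a fixed number of iterations
per imputed dataset.

Pooling is deliberately non-standard: instead of Rubin's rules, the m
completed datasets are collapsed into ONE analysis dataset whose
imputed cells take the most frequent category across imputations (ties
broken by the lowest category code), and all analyses run on that single
pooled dataset.  The pooled table records per-cell provenance
(observed vs imputed) in one boolean column per imputable covariate.

Only covariates are imputed — never the outcome, sex or year of birth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .synthetic_cohort import MASKABLE_COVARIATES

logger = logging.getLogger(__name__)

#: always-complete predictors added to every conditional model
_BASE_PREDICTORS = ["ethnicity", "sex", "age", "period", "ghq_total"]


@dataclass
class ImputationConfig:
    n_imputations: int = 5
    n_iterations: int = 10
    seed: int = 0
    variables: list[str] | None = None  # default: maskable covariates present

    def validate(self) -> None:
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def _predictor_matrix(
    rows: pd.DataFrame, variables: list[str], target: str
) -> np.ndarray:
    """One-hot design of all covariates except the target, plus the
    always-complete base predictors."""
    pieces = []
    for v in variables:
        if v == target:
            continue
        pieces.append(pd.get_dummies(rows[v].astype("category"), prefix=v))
    for v in _BASE_PREDICTORS:
        if v not in rows.columns:
            continue
        if rows[v].dtype == object:
            pieces.append(pd.get_dummies(rows[v].astype("category"), prefix=v))
        else:
            col = rows[v].astype(float)
            sd = col.std()
            pieces.append((col - col.mean()) / (sd if sd > 0 else 1.0))
    X = pd.concat(pieces, axis=1)
    return X.to_numpy(dtype=float)


def chained_imputation(
    rows: pd.DataFrame, config: ImputationConfig
) -> list[pd.DataFrame]:
    """Produce ``n_imputations`` completed copies of ``rows``.

    Missing cells are initialised by sampling each variable's observed
    marginal, then refined by ``n_iterations`` chained sweeps.
    Imputations differ only through their RNG streams; the whole
    procedure is deterministic given ``config.seed``.
    """
    config.validate()
    variables = config.variables
    if variables is None:
        variables = [v for v in MASKABLE_COVARIATES if v in rows.columns]
    missing_mask = {v: rows[v].isna().to_numpy() for v in variables}
    for v in variables:
        if missing_mask[v].all():
            raise ValueError(f"variable {v!r} is 100% missing; cannot impute")

    incomplete = [v for v in variables if missing_mask[v].any()]
    if not incomplete:
        return [rows.copy() for _ in range(config.n_imputations)]

    completed: list[pd.DataFrame] = []
    for m in range(config.n_imputations):
        rng = np.random.default_rng([config.seed, 104729, m])
        data = rows.copy()
        # initialise from observed marginals
        for v in incomplete:
            obs_vals = rows.loc[~missing_mask[v], v].to_numpy()
            fill = rng.choice(obs_vals, size=int(missing_mask[v].sum()))
            data.loc[missing_mask[v], v] = fill

        for _ in range(config.n_iterations):
            for v in incomplete:
                miss = missing_mask[v]
                y_obs = rows.loc[~miss, v].astype(int).to_numpy()
                classes = np.unique(y_obs)
                if classes.size == 1:
                    data.loc[miss, v] = classes[0]
                    continue
                X = _predictor_matrix(data, variables, v)
                clf = LogisticRegression(
                    C=1.0, max_iter=200, solver="lbfgs"
                )  # L2 penalty stabilises sparse categories
                clf.fit(X[~miss], y_obs)
                proba = clf.predict_proba(X[miss])
                cum = np.cumsum(proba, axis=1)
                u = rng.random(proba.shape[0])[:, None]
                draw_idx = (u > cum).sum(axis=1)
                data.loc[miss, v] = clf.classes_[draw_idx]
        completed.append(data)
    return completed


def pool_by_mode(
    imputed: list[pd.DataFrame],
    original: pd.DataFrame,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse completed datasets into one pooled dataset by cell mode.

    Observed cells are taken verbatim from ``original``; each originally
    missing cell takes the most frequent imputed category across the m
    datasets, ties resolved toward the lowest category code.  Adds a
    boolean ``<var>_imputed`` provenance column per imputable covariate.
    """
    if not imputed:
        raise ValueError("no imputed datasets to pool")
    shape = imputed[0].shape
    for d in imputed[1:]:
        if d.shape != shape:
            raise ValueError("imputed datasets differ in shape")
    if shape[0] != len(original):
        raise ValueError("imputed datasets do not match the original rows")
    if variables is None:
        variables = [v for v in MASKABLE_COVARIATES if v in original.columns]

    pooled = original.copy()
    for v in variables:
        miss = original[v].isna().to_numpy()
        pooled[f"{v}_imputed"] = miss
        if not miss.any():
            continue
        stack = np.stack(
            [d.loc[miss, v].astype(float).to_numpy() for d in imputed]
        )  # (m, n_missing)
        levels = np.unique(stack)
        counts = (stack[None, :, :] == levels[:, None, None]).sum(axis=1)
        # argmax over ascending levels -> lowest code wins ties
        pooled.loc[miss, v] = levels[np.argmax(counts, axis=0)]
    return pooled
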