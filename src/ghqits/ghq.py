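"""Scoring of the 12-item General Health Questionnaire (GHQ-12).

Each item is answered on a four-point Likert scale coded 0–3; the Likert
total over the twelve items gives a continuous psychological-distress score
ranging from 0 (least distress) to 36 (most distress).  Binary "caseness"
scoring (0-0-1-1) is deliberately not offered: the analyses in this package
treat distress as a continuous outcome on the 0–36 scale.

A record is only scoreable when all twelve items are present; partial
responses are never prorated, they simply make that interview ineligible.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_ITEMS = 12
MIN_SCORE = 0
MAX_SCORE = 36

#: names of the item columns in cohort tables
ITEM_COLUMNS = [f"ghq_{i}" for i in range(1, N_ITEMS + 1)]


class GhqIncompleteError(ValueError):
    """Raised when a response is missing one or more of the 12 items."""


class GhqInvalidItemError(ValueError):
    """Raised when an item value falls outside the Likert range {0,1,2,3}."""


def score_ghq12(items: Sequence[float | int | None] | Iterable) -> int:
    """Likert-score a single 12-item response.

    Parameters
    ----------
    items
        Exactly twelve item responses, each in {0, 1, 2, 3}.  ``None`` or
        NaN marks an absent item.

    Returns
    -------
    int
        The total score in [0, 36].

    Raises
    ------
    GhqIncompleteError
        If any item is absent (the interview then has an incomplete
        outcome and is ineligible for analysis).
    GhqInvalidItemError
        If the response does not have exactly 12 items or an item lies
        outside {0, 1, 2, 3}.
    """
    vals = list(items)
    if len(vals) != N_ITEMS:
        raise GhqInvalidItemError(
            f"GHQ-12 response must have exactly {N_ITEMS} items, got {len(vals)}"
        )
    total = 0
    for i, v in enumerate(vals):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise GhqIncompleteError(f"item {i + 1} is absent; outcome incomplete")
        iv = int(v)
        if iv != v or iv not in (0, 1, 2, 3):
            raise GhqInvalidItemError(f"item {i + 1} value {v!r} not in {{0,1,2,3}}")
        total += iv
    return total


def add_ghq_totals(
    observations: pd.DataFrame,
    *,
    total_column: str = "ghq_total",
) -> pd.DataFrame:
    """Attach a ``ghq_total`` column to an observation table.

    Accepts either the twelve item columns (``ghq_1`` … ``ghq_12``), a
    precomputed total column, or both.  Rows whose items are incomplete
    get a missing total (they are dropped later by the eligibility
    filters).  When items and a precomputed total are both present but
    disagree, the record is flagged and rejected (total set missing).

    Returns a copy; the input is not modified.
    """
    obs = observations.copy()
    have_items = all(c in obs.columns for c in ITEM_COLUMNS)
    have_total = total_column in obs.columns

    if not have_items and not have_total:
        raise ValueError(
            f"observations carry neither the {N_ITEMS} item columns nor "
            f"a {total_column!r} column"
        )

    if have_items:
        items = obs[ITEM_COLUMNS].to_numpy(dtype=float)
        complete = ~np.isnan(items).any(axis=1)
        valid = complete & np.isin(items, [0.0, 1.0, 2.0, 3.0]).all(axis=1)
        item_total = np.where(valid, np.nansum(items, axis=1), np.nan)
    if have_total:
        given = pd.to_numeric(obs[total_column], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isnan(given) & ((given < MIN_SCORE) | (given > MAX_SCORE))
        given = np.where(bad, np.nan, given)

    if have_items and have_total:
        conflict = (~np.isnan(item_total)) & (~np.isnan(given)) & (item_total != given)
        n_conflict = int(conflict.sum())
        if n_conflict:
            logger.warning(
                "%d records have item totals disagreeing with the precomputed "
                "total; rejecting them",
                n_conflict,
            )
        total = np.where(np.isnan(item_total), given, item_total)
        total[conflict] = np.nan
    elif have_items:
        total = item_total
    else:
        total = given

    obs[total_column] = total
    return obs
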