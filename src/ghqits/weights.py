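"""Bespoke longitudinal inverse-probability-of-response weights.

Panel attrition is corrected by weighting each analysis row by the
reciprocal of the empirical response probability in its (sampling
stratum, exposure period) cell.  The eligibility base of a cell is the
included cohort — every person retained by the eligibility filters —
and a person "responds" in a period if they contribute at least one
analysis row to it.  Probabilities are raw cell proportions: no model
smoothing, no trimming; an extreme weight signals a configuration
problem and is surfaced in the log rather than hidden.

The construction satisfies the Horvitz–Thompson identity exactly: within
each cell the responders' weights sum to the eligible count.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EmptyResponseCellError(ValueError):
    """A cell has eligible persons but no responders at all."""


class UncoveredCellError(KeyError):
    """Rows fall in a (stratum, period) cell absent from the weight table."""


def estimate_response_probabilities(
    persons: pd.DataFrame,
    rows: pd.DataFrame,
    periods: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Build the weight table from the included cohort and its rows.

    Parameters
    ----------
    persons
        Included cohort, one row per person, with ``person_id`` and
        ``stratum`` columns (everyone here has ≥1 complete outcome).
    rows
        Analysis rows with ``person_id``, ``stratum`` and ``period``.
    periods
        Period indices to tabulate.

    Returns
    -------
    pandas.DataFrame
        Columns ``stratum, period, eligible, responders, probability,
        weight``.  Cells with zero eligible persons are absent.

    Raises
    ------
    EmptyResponseCellError
        If a cell has eligible persons but zero responders (there are no
        rows to weight, but the condition must be reported).
    """
    eligible = persons.groupby("stratum")["person_id"].nunique()
    records = []
    for s, n_elig in eligible.items():
        in_stratum = rows["stratum"] == s
        for p in periods:
            resp = rows.loc[in_stratum & (rows["period"] == p), "person_id"].nunique()
            if n_elig == 0:
                continue
            if resp == 0:
                raise EmptyResponseCellError(
                    f"stratum {s}, period {p}: {n_elig} eligible persons "
                    "but no responders"
                )
            prob = resp / n_elig
            records.append(
                {
                    "stratum": s,
                    "period": p,
                    "eligible": int(n_elig),
                    "responders": int(resp),
                    "probability": prob,
                    "weight": 1.0 / prob,
                }
            )
    table = pd.DataFrame(records)
    wmax = table["weight"].max()
    if wmax > 10:
        logger.warning("maximum response weight is %.1f; check the design", wmax)
    return table


def attach_weights(
    rows: pd.DataFrame, table: pd.DataFrame, mode: str = "weighted"
) -> pd.DataFrame:
    """Attach the ``weight`` column to analysis rows.

    ``mode="weighted"`` looks each row's (stratum, period) up in the
    table; ``mode="unweighted"`` sets every weight to 1 (the sensitivity
    analysis without the weighting strategy).
    """
    out = rows.copy()
    if mode == "unweighted":
        out["weight"] = 1.0
        return out
    if mode != "weighted":
        raise ValueError(f"mode must be 'weighted' or 'unweighted', got {mode!r}")
    lut = table.set_index(["stratum", "period"])["weight"]
    key = pd.MultiIndex.from_frame(out[["stratum", "period"]])
    missing = ~key.isin(lut.index)
    if missing.any():
        cells = sorted(set(map(tuple, out.loc[missing, ["stratum", "period"]].values)))
        raise UncoveredCellError(
            f"weight table does not cover cells {cells[:5]}"
            + ("..." if len(cells) > 5 else "")
        )
    out["weight"] = lut.loc[key].to_numpy()
    return out
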