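"""Klein Sexual Orientation Grid scoring.

The grid crosses 7 orientation components with 3 timeframes (past, present,
ideal); each cell is rated 1 (other sex only) to 7 (same sex only). The
score is the arithmetic mean of the rated cells, so 1 anchors strict
heterosexuality, 3.5 strict bisexuality and 7 strict homosexuality. Missing
cells are dropped from the mean rather than imputed; an all-missing grid
yields a missing score.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def ksog_score(ratings) -> float:
    """Mean of the non-missing cell ratings; NaN if all are missing."""
    vals = np.asarray(pd.Series(ratings, dtype=float).dropna())
    if vals.size == 0:
        return math.nan
    if ((vals < 1) | (vals > 7)).any():
        raise ValueError("KSOG ratings must lie in [1, 7]")
    return float(vals.mean())


def score_cohort(cells: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: ksog_score and n_cells_used."""
    rows = []
    for pid, sub in cells.groupby("participant_id", sort=True):
        rated = sub["rating"].dropna()
        rows.append(
            {
                "participant_id": pid,
                "ksog_score": ksog_score(sub["rating"]),
                "n_cells_used": int(len(rated)),
            }
        )
    return pd.DataFrame(rows)
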