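"""FAST cumulative-record construction and learning-slope scoring.

Each 50-trial test block yields a cumulative record (running count of
correct responses against trial order, timeouts counting as incorrect); the
learning rate is the ordinary least-squares slope of that record, and the
participant's score is the straight-block slope minus the lesbian-block
slope. Positive differences mean faster acquisition under the straight-block
contingencies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import BlockRule, Phase, SlopeSet


class FastScoringError(ValueError):
    pass


def cumulative_record(block_trials: pd.DataFrame) -> np.ndarray:
    """Running count of correct responses of one test block, in trial order.

    ``y[i] = #{j <= i : correct_j}`` (the count at trial i includes trial i).
    Duplicate or missing trial indices are rejected.
    """
    idx = block_trials["trial_index"].to_numpy()
    n = len(idx)
    if n == 0:
        raise FastScoringError("empty block")
    expected = np.arange(1, n + 1)
    if not np.array_equal(np.sort(idx), expected):
        raise FastScoringError("duplicate or missing trial_index in block")
    order = np.argsort(idx)
    correct = block_trials["correct"].to_numpy()[order].astype(int)
    return np.cumsum(correct)


def learning_slope(record: np.ndarray) -> float:
    """OLS slope of the cumulative record on trial order (intercept discarded)."""
    record = np.asarray(record, dtype=float)
    n = len(record)
    if n < 2:
        raise FastScoringError("record must have length >= 2")
    t = np.arange(1, n + 1, dtype=float)
    tc = t - t.mean()
    return float(tc @ (record - record.mean()) / (tc @ tc))


def slope_difference(slope_straight: float, slope_lesbian: float) -> float:
    return slope_straight - slope_lesbian


def score_participant(trials: pd.DataFrame) -> SlopeSet:
    """Block slopes and their difference for one participant's FAST log."""
    pid = str(trials["participant_id"].iloc[0])
    test = trials[trials["phase"] == Phase.TEST.value]
    slopes = {}
    for rule in (BlockRule.STRAIGHT.value, BlockRule.LESBIAN.value):
        block = test[test["block_rule"] == rule]
        if block.empty:
            raise FastScoringError(f"{pid}: missing {rule} test block")
        slopes[rule] = learning_slope(cumulative_record(block))
    return SlopeSet(
        participant_id=pid,
        slope_straight=slopes[BlockRule.STRAIGHT.value],
        slope_lesbian=slopes[BlockRule.LESBIAN.value],
    )


def score_cohort(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: slope_straight, slope_lesbian, slope_difference."""
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        ss = score_participant(sub)
        rows.append(
            {
                "participant_id": pid,
                "slope_straight": ss.slope_straight,
                "slope_lesbian": ss.slope_lesbian,
                "slope_difference": ss.slope_difference,
            }
        )
    return pd.DataFrame(rows)
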