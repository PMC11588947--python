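"""IRAP practice gate, latency filters, and the D-score algorithm.

The D score is a per-participant standardized latency difference between the
two block rules, in the tradition of the IAT D statistic: for every pair of
test blocks and every trial-type, the mean latency under the straight-block
rule is subtracted from the mean latency under the lesbian-block rule and
the difference divided by the sample standard deviation of the latencies
pooled over both blocks of that pair for that trial-type. Positive scores
therefore mean faster responding under the straight-block rule.

Processing order is fixed: practice latencies are discarded, test latencies
above 10,000 ms are dropped, participants with more than 10% of test trials
under 300 ms are excluded, and only then are D scores computed.

Boundary semantics (read literally from the procedure's wording): the
latency filter is strictly *above* 10,000 ms; the fast-responder rule is
strictly *more than* 10%; the practice accuracy criterion is inclusive (at
least 80%); the practice median-latency criterion is strict (*less than*
2000 ms). The fast-responder proportion is taken over all test trials,
before the 10,000 ms filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    MAX_PRACTICE_PAIRS,
    N_TEST_PAIRS,
    N_TRIAL_TYPES,
    BlockRule,
    DScoreSet,
    ExclusionReason,
    Phase,
)

LATENCY_CEILING_MS = 10_000.0
FAST_RESPONSE_MS = 300.0
FAST_RESPONDER_PROP = 0.10
PRACTICE_ACCURACY_MIN = 0.80
PRACTICE_MEDIAN_MAX_MS = 2000.0


class ScoringError(ValueError):
    """A participant's trials cannot be scored; message names the cell."""


def practice_gate(trials: pd.DataFrame) -> tuple[bool, int]:
    """Adjudicate the practice-block performance criterion for one participant.

    Eligible iff some practice pair (among at most three attempts) reaches,
    in each of its two blocks, first-response accuracy >= 80% AND a median
    latency < 2000 ms. Returns ``(eligible, pairs_used)`` where pairs_used is
    the 1-based index of the first passing pair, or the number of attempts
    (capped at 3) if none passed.
    """
    practice = trials[trials["phase"] == Phase.PRACTICE.value]
    if practice.empty:
        raise ScoringError("no practice-phase trials: cannot adjudicate eligibility")
    pairs = sorted(practice["pair_index"].unique())[:MAX_PRACTICE_PAIRS]
    for pair in pairs:
        sub = practice[practice["pair_index"] == pair]
        blocks = sub.groupby("block_rule")
        if len(blocks) != 2:
            continue
        ok = all(
            block["first_response_correct"].mean() >= PRACTICE_ACCURACY_MIN
            and block["latency_ms"].median() < PRACTICE_MEDIAN_MAX_MS
            for _, block in blocks
        )
        if ok:
            return True, int(pair)
    return False, min(len(pairs), MAX_PRACTICE_PAIRS)


def apply_trial_filter(test_trials: pd.DataFrame) -> pd.DataFrame:
    """Drop test trials with latency strictly above 10,000 ms."""
    return test_trials[test_trials["latency_ms"] <= LATENCY_CEILING_MS]


def fast_responder_check(test_trials: pd.DataFrame) -> bool:
    """True iff strictly more than 10% of test trials are under 300 ms.

    Computed over all test trials, before the 10,000 ms filter.
    """
    n = len(test_trials)
    if n == 0:
        return False
    n_fast = int((test_trials["latency_ms"] < FAST_RESPONSE_MS).sum())
    return n_fast / n > FAST_RESPONDER_PROP


def compute_d_scores(test_trials: pd.DataFrame, participant_id: str = "") -> DScoreSet:
    """Steps 4-8 of the D algorithm for one eligible, retained participant.

    Requires 3 test pairs with both block rules present and at least two
    retained latencies per (pair, trial-type, rule) cell; a cell with fewer
    latencies, or a zero pooled SD, raises :class:`ScoringError` naming the
    offending (pair, trial_type).
    """
    if not participant_id and len(test_trials):
        participant_id = str(test_trials["participant_id"].iloc[0])
    per_pair = np.full((N_TEST_PAIRS, N_TRIAL_TYPES), np.nan)
    for p in range(1, N_TEST_PAIRS + 1):
        pair = test_trials[test_trials["pair_index"] == p]
        for t in range(1, N_TRIAL_TYPES + 1):
            cell = pair[pair["trial_type"] == t]
            lat_l = cell.loc[
                cell["block_rule"] == BlockRule.LESBIAN.value, "latency_ms"
            ].to_numpy()
            lat_s = cell.loc[
                cell["block_rule"] == BlockRule.STRAIGHT.value, "latency_ms"
            ].to_numpy()
            if len(lat_l) < 2 or len(lat_s) < 2:
                raise ScoringError(
                    f"{participant_id}: <2 retained latencies in "
                    f"(pair {p}, trial_type {t})"
                )
            pooled = np.concatenate([lat_l, lat_s])
            sd = pooled.std(ddof=1)
            if sd == 0.0:
                raise ScoringError(
                    f"{participant_id}: zero pooled SD in (pair {p}, trial_type {t})"
                )
            per_pair[p - 1, t - 1] = (lat_l.mean() - lat_s.mean()) / sd
    return DScoreSet(participant_id=participant_id, per_pair=per_pair)


def score_participant(trials: pd.DataFrame) -> DScoreSet:
    """Full pipeline for one participant: gate, filters, then D scores."""
    pid = str(trials["participant_id"].iloc[0])
    eligible, _ = practice_gate(trials)
    if not eligible:
        return DScoreSet(pid, excluded_reason=ExclusionReason.PRACTICE_FAIL)
    test = trials[trials["phase"] == Phase.TEST.value]
    if fast_responder_check(test):
        return DScoreSet(pid, excluded_reason=ExclusionReason.FAST_RESPONDER)
    return compute_d_scores(apply_trial_filter(test), pid)


def score_cohort(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every participant in an IRAP log.

    Returns one row per participant with columns ``d_tt1..d_tt4``, ``d_avg``,
    ``d_male`` (mean of trial-types 1-2), ``d_female`` (mean of 3-4) and
    ``excluded_reason``; excluded participants carry NaN scores.
    """
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        ds = score_participant(sub)
        per_type = ds.per_type
        rows.append(
            {
                "participant_id": pid,
                "d_tt1": per_type[0],
                "d_tt2": per_type[1],
                "d_tt3": per_type[2],
                "d_tt4": per_type[3],
                "d_avg": ds.averaged,
                "d_male": ds.d_male,
                "d_female": ds.d_female,
                "excluded_reason": ds.excluded_reason.value,
            }
        )
    return pd.DataFrame(rows)
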