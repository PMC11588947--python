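"""CSV interchange for trial-level task logs and participant metadata.

One flat schema per artifact, one row per trial (or per KSOG cell). Files
are rejected as a whole on any malformed row, with the offending row number
(1-based, counting the header as row 1) named in the error. Structural
deviations from the canonical session layout (e.g. a 23-trial test block in
an aborted session) load fine but raise :class:`StructureWarning`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    FAST_TEST_TRIALS,
    KSOG_ITEMS,
    KSOG_TIMEFRAMES,
    N_TEST_PAIRS,
    TRIALS_PER_IRAP_BLOCK,
    BlockRule,
    Orientation,
    Phase,
    StimulusClass,
)

IRAP_COLUMNS = [
    "participant_id",
    "phase",
    "pair_index",
    "block_rule",
    "trial_type",
    "latency_ms",
    "first_response_correct",
]
FAST_COLUMNS = [
    "participant_id",
    "phase",
    "block_rule",
    "trial_index",
    "stimulus_class",
    "correct",
    "timeout",
]
KSOG_COLUMNS = ["participant_id", "item", "timeframe", "rating"]
MANIFEST_COLUMNS = ["participant_id", "orientation"]

_BOOL_MAP = {"true": True, "false": False}


class LoadError(ValueError):
    """A file failed validation; no partial data is returned."""


class StructureWarning(UserWarning):
    """A participant's session deviates from the canonical block layout."""


def _read_raw(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise LoadError(f"{path}: empty file") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing column(s) {missing}")
    return df[columns]


def _fail(path: Path | str, mask: pd.Series, what: str) -> None:
    if mask.any():
        # +2: 1-based data rows start after the header line
        row = int(np.flatnonzero(mask.to_numpy())[0]) + 2
        raise LoadError(f"{path}: {what} on row {row}")


def _parse_enum(df: pd.DataFrame, col: str, allowed: set[str], path) -> None:
    _fail(path, ~df[col].isin(allowed), f"unknown {col} value")


def _parse_bool(df: pd.DataFrame, col: str, path) -> pd.Series:
    low = df[col].str.lower()
    _fail(path, ~low.isin(_BOOL_MAP), f"unparseable boolean in {col}")
    return low.map(_BOOL_MAP)


def _parse_num(df: pd.DataFrame, col: str, path, *, integer: bool = False) -> pd.Series:
    num = pd.to_numeric(df[col], errors="coerce")
    _fail(path, num.isna(), f"unparseable {col}")
    if integer:
        _fail(path, num != num.round(), f"non-integer {col}")
        return num.astype(int)
    # exact strtod parse; to_numeric's fast path can be off by one ULP
    return df[col].astype(float)


def read_irap_log(path: str | Path) -> pd.DataFrame:
    """Load an IRAP trial log, validating every row.

    Returns a DataFrame with one row per trial and typed columns. Counts of
    test trials per (participant, pair, block) are checked against the
    canonical 3 pairs x 2 blocks x 24 trials and reported as
    :class:`StructureWarning`, not errors.
    """
    df = _read_raw(path, IRAP_COLUMNS)
    _parse_enum(df, "phase", {p.value for p in Phase}, path)
    _parse_enum(df, "block_rule", {b.value for b in BlockRule}, path)
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "phase": df["phase"],
            "pair_index": _parse_num(df, "pair_index", path, integer=True),
            "block_rule": df["block_rule"],
            "trial_type": _parse_num(df, "trial_type", path, integer=True),
            "latency_ms": _parse_num(df, "latency_ms", path),
            "first_response_correct": _parse_bool(df, "first_response_correct", path),
        }
    )
    _fail(path, ~out["trial_type"].isin([1, 2, 3, 4]), "trial_type outside 1..4")
    _fail(path, out["latency_ms"] <= 0, "non-positive latency_ms")
    _fail(path, out["pair_index"] < 1, "pair_index < 1")
    validate_irap_structure(out)
    return out


def validate_irap_structure(trials: pd.DataFrame) -> list[str]:
    """Warn (and return messages) for participants whose test phase deviates
    from 3 pairs x 2 blocks x 24 trials with each trial-type 6x per block."""
    msgs: list[str] = []
    test = trials[trials["phase"] == Phase.TEST.value]
    for pid, sub in test.groupby("participant_id", sort=True):
        pairs = sorted(sub["pair_index"].unique())
        if pairs != list(range(1, N_TEST_PAIRS + 1)):
            msgs.append(f"{pid}: test pair indices {pairs} != 1..{N_TEST_PAIRS}")
        counts = sub.groupby(["pair_index", "block_rule"]).size()
        if len(counts) != N_TEST_PAIRS * 2 or (counts != TRIALS_PER_IRAP_BLOCK).any():
            msgs.append(f"{pid}: test block trial counts deviate from 24 per block")
        else:
            tt = sub.groupby(["pair_index", "block_rule", "trial_type"]).size()
            if (tt != TRIALS_PER_IRAP_BLOCK // 4).any():
                msgs.append(f"{pid}: trial-types not balanced 6-each within blocks")
    for m in msgs:
        warnings.warn(m, StructureWarning, stacklevel=3)
    return msgs


def read_fast_log(path: str | Path) -> pd.DataFrame:
    """Load a FAST trial log (one row per trial)."""
    df = _read_raw(path, FAST_COLUMNS)
    _parse_enum(df, "phase", {p.value for p in Phase}, path)
    _parse_enum(df, "block_rule", {b.value for b in BlockRule}, path)
    _parse_enum(df, "stimulus_class", {s.value for s in StimulusClass}, path)
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "phase": df["phase"],
            "block_rule": df["block_rule"],
            "trial_index": _parse_num(df, "trial_index", path, integer=True),
            "stimulus_class": df["stimulus_class"],
            "correct": _parse_bool(df, "correct", path),
            "timeout": _parse_bool(df, "timeout", path),
        }
    )
    _fail(path, out["timeout"] & out["correct"], "timeout trial marked correct")
    _fail(path, out["trial_index"] < 1, "trial_index < 1")
    validate_fast_structure(out)
    return out


def validate_fast_structure(trials: pd.DataFrame) -> list[str]:
    """Warn for participants without exactly one 50-trial test block per rule."""
    msgs: list[str] = []
    test = trials[trials["phase"] == Phase.TEST.value]
    for pid, sub in test.groupby("participant_id", sort=True):
        counts = sub.groupby("block_rule").size()
        ok = len(counts) == 2 and (counts == FAST_TEST_TRIALS).all()
        if ok:
            for _, block in sub.groupby("block_rule"):
                idx = sorted(block["trial_index"])
                if idx != list(range(1, FAST_TEST_TRIALS + 1)):
                    ok = False
        if not ok:
            msgs.append(f"{pid}: FAST test blocks deviate from 2 x 50 trials")
    for m in msgs:
        warnings.warn(m, StructureWarning, stacklevel=3)
    return msgs


def read_ksog(path: str | Path) -> pd.DataFrame:
    """Load KSOG cell ratings: participant x item (1..7) x timeframe, rating
    1..7 or empty (missing)."""
    df = _read_raw(path, KSOG_COLUMNS)
    _parse_enum(df, "timeframe", set(KSOG_TIMEFRAMES), path)
    item = _parse_num(df, "item", path, integer=True)
    _fail(path, ~item.isin(range(1, KSOG_ITEMS + 1)), "item outside 1..7")
    rating = pd.to_numeric(df["rating"].replace("", np.nan), errors="coerce")
    bad = df["rating"].ne("") & (
        rating.isna() | ~rating.isin(range(1, 8))
    )
    _fail(path, bad, "rating outside 1..7")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"],
            "item": item,
            "timeframe": df["timeframe"],
            "rating": rating,
        }
    )
    dup = out.duplicated(["participant_id", "item", "timeframe"])
    _fail(path, dup, "duplicate KSOG cell")
    over = out.groupby("participant_id").size()
    if (over > KSOG_ITEMS * len(KSOG_TIMEFRAMES)).any():
        raise LoadError(f"{path}: more than 21 KSOG cells for a participant")
    return out


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load the participant manifest; orientation is a closed two-level enum."""
    df = _read_raw(path, MANIFEST_COLUMNS)
    _parse_enum(df, "orientation", {o.value for o in Orientation}, path)
    dup = df.duplicated("participant_id")
    _fail(path, dup, "duplicate participant_id")
    return df.copy()


def _write(df: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    out = df[columns].copy()
    for c in columns:
        if out[c].dtype == bool:
            out[c] = out[c].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def write_irap_log(trials: pd.DataFrame, path: str | Path) -> None:
    _write(trials, path, IRAP_COLUMNS)


def write_fast_log(trials: pd.DataFrame, path: str | Path) -> None:
    _write(trials, path, FAST_COLUMNS)


def write_ksog(cells: pd.DataFrame, path: str | Path) -> None:
    out = cells[KSOG_COLUMNS].copy()
    out["rating"] = out["rating"].map(
        lambda r: "" if pd.isna(r) else str(int(r))
    )
    out.to_csv(path, index=False)


def write_manifest(participants: pd.DataFrame, path: str | Path) -> None:
    _write(participants, path, MANIFEST_COLUMNS)
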