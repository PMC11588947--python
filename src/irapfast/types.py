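"""Shared domain types for IRAP/FAST/KSOG trial-level data and derived scores.

Trial collections are carried as pandas DataFrames (one row per trial); the
dataclasses here hold single-participant results and enumerate the closed
vocabularies used throughout the pipeline.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

N_TRIAL_TYPES = 4
TRIALS_PER_IRAP_BLOCK = 24
N_TEST_PAIRS = 3
MAX_PRACTICE_PAIRS = 3
FAST_TEST_TRIALS = 50
FAST_PRACTICE_TRIALS = 16
KSOG_ITEMS = 7
KSOG_TIMEFRAMES = ("past", "present", "ideal")


class Orientation(str, enum.Enum):
    """Self-declared stable partner preference; the study admits two levels."""

    STRAIGHT = "straight"
    LESBIAN = "lesbian"


class Phase(str, enum.Enum):
    PRACTICE = "practice"
    TEST = "test"


class BlockRule(str, enum.Enum):
    """The response contingency in force for a block."""

    STRAIGHT = "straight_block"
    LESBIAN = "lesbian_block"


class StimulusClass(str, enum.Enum):
    MALE_PIC = "male_pic"
    FEMALE_PIC = "female_pic"
    POS_WORD = "pos_word"
    NEG_WORD = "neg_word"


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    FAST_RESPONDER = "fast_responder"
    PRACTICE_FAIL = "practice_fail"


@dataclass
class Participant:
    id: str
    orientation: Orientation
    ksog_score: float | None = None
    irap_eligible: bool = True


@dataclass
class DScoreSet:
    """Per-pair, per-trial-type and averaged D scores for one participant.

    ``per_pair`` is a (3 pairs x 4 trial-types) array of D_{p,t};
    ``per_type`` averages over pairs, ``averaged`` over trial-types.
    Positive values mean faster responding under the straight-block rule.
    """

    participant_id: str
    per_pair: np.ndarray = field(default_factory=lambda: np.full((3, 4), np.nan))
    excluded_reason: ExclusionReason = ExclusionReason.NONE

    @property
    def per_type(self) -> np.ndarray:
        return self.per_pair.mean(axis=0)

    @property
    def averaged(self) -> float:
        return float(self.per_type.mean())

    @property
    def d_male(self) -> float:
        """Mean over the two male-picture trial-types (1 and 2)."""
        return float(self.per_type[:2].mean())

    @property
    def d_female(self) -> float:
        """Mean over the two female-picture trial-types (3 and 4)."""
        return float(self.per_type[2:].mean())

    def __post_init__(self) -> None:
        self.per_pair = np.asarray(self.per_pair, dtype=float)
        if self.per_pair.shape != (N_TEST_PAIRS, N_TRIAL_TYPES):
            raise ValueError(
                f"per_pair must be {N_TEST_PAIRS}x{N_TRIAL_TYPES}, "
                f"got {self.per_pair.shape}"
            )
        if self.excluded_reason is ExclusionReason.NONE and not np.all(
            np.isfinite(self.per_pair)
        ):
            raise ValueError("non-excluded DScoreSet must have finite scores")


@dataclass
class SlopeSet:
    """Per-block FAST learning slopes and their difference (straight - lesbian)."""

    participant_id: str
    slope_straight: float
    slope_lesbian: float

    @property
    def slope_difference(self) -> float:
        return self.slope_straight - self.slope_lesbian


@dataclass
class EffectReport:
    """Two-group comparison bundle.

    ``w_statistic`` is the Mann-Whitney pair count for the first (straight)
    group with ties half-weighted; ``r_estimator`` = W/(n1*n2), which equals
    the Vargha-Delaney A when W counts the same direction.
    """

    w_statistic: float | None = None
    r_estimator: float | None = None
    w_p_value: float | None = None
    cliffs_delta: float | None = None
    vd_a: float | None = None
    t_statistic: float | None = None
    t_df: float | None = None
    t_p_value: float | None = None
    cohens_d: float | None = None

    def __post_init__(self) -> None:
        if self.cliffs_delta is not None and self.vd_a is not None:
            assert math.isclose(self.vd_a, (self.cliffs_delta + 1.0) / 2.0)


@dataclass
class RocReport:
    """ROC curve with its tie-corrected AUC.

    ``specificity`` runs 1 -> 0; ``direction`` declares which class is
    expected to score higher.
    """

    specificity: np.ndarray
    sensitivity: np.ndarray
    auc: float
    direction: str = "controls_gt_cases"
    variance: float | None = None
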