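"""Synthetic cohort generator for IRAP, FAST, and KSOG trial-level data.

The generator reproduces the structure of the study design — 33 straight and
25 lesbian participants; IRAP with up to three practice block-pairs followed
by exactly three test pairs of two 24-trial blocks (four trial-types, six
each, randomized within block); FAST with one 16-trial practice block and
two 50-trial test blocks in random order; a 7 x 3 KSOG grid on a 1-7 integer
scale — together with the statistical structure the downstream analysis
assumes.

Latencies follow a log-normal model: log latency = base + participant
intercept + incoherence increment + noise, where the increment applies in
the block whose rule is history-incoherent for the participant's orientation
(the lesbian-rule block for straight participants and vice versa) and is
parameterized per trial-type. Because the D score is scale- and
shift-invariant, the base and intercept are behaviourally arbitrary; group
D-score moments are controlled by the increments, the residual log-SD and a
participant-level increment shift. FAST accuracy follows a saturating
learning curve P(correct at t) = p_inf - (p_inf - p0) exp(-kappa t) with a
per-orientation, per-block learning rate kappa and an independent timeout
process that forces an incorrect response.

Default parameters are moment-matched to the published group summaries
(group means/SDs of the averaged D score and the FAST slope differences, and
the lesbian group's per-block slope means) and shipped in ``defaults.yaml``.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    FAST_PRACTICE_TRIALS,
    FAST_TEST_TRIALS,
    KSOG_ITEMS,
    KSOG_TIMEFRAMES,
    MAX_PRACTICE_PAIRS,
    N_TEST_PAIRS,
    BlockRule,
    Orientation,
    Phase,
    StimulusClass,
)

_STIM_CLASSES = [s.value for s in StimulusClass]
_ORIENTATIONS = [Orientation.STRAIGHT.value, Orientation.LESBIAN.value]
_RULES = [BlockRule.STRAIGHT.value, BlockRule.LESBIAN.value]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults live in ``defaults.yaml``."""

    n_straight: int = 33
    n_lesbian: int = 25
    seed: int = 0
    # IRAP latency model
    base_log_latency: float = 7.313  # log ms; exp() ~ 1500 ms median
    participant_sd: float = 0.15  # SD of the random intercept (log scale)
    residual_log_sd: float = 0.25  # trial noise (log scale)
    # mean log-latency increment in the history-incoherent block, per
    # trial-type (1..4), per orientation
    irap_effect_matrix: dict = field(
        default_factory=lambda: {
            "straight": [0.1050, 0.0735, -0.0341, -0.0394],
            "lesbian": [-0.0111, 0.1084, 0.2168, 0.1612],
        }
    )
    # SD of the participant-level shift of the increment, per orientation
    effect_participant_sd: dict = field(
        default_factory=lambda: {"straight": 0.07, "lesbian": 0.09}
    )
    long_latency_rate: float = 0.01  # trials replaced by a >10 s latency
    fast_responder_rate: float = 0.0  # participants emitting many <300 ms trials
    fast_responder_trial_rate: float = 0.25
    practice_fail_rate: float = 0.557  # per practice pair (Bernoulli)
    # FAST learning model
    fast_p0: float = 0.35
    fast_pinf: float = 0.95
    fast_learn_rate: dict = field(
        default_factory=lambda: {
            "straight": {"straight_block": 0.0150, "lesbian_block": 0.0130},
            "lesbian": {"straight_block": 0.0054, "lesbian_block": 0.0271},
        }
    )
    # log-scale SD of the per-participant, per-block kappa multiplier
    fast_kappa_sd: float = 0.6
    fast_timeout_rate: float = 0.02
    # KSOG
    ksog_group_means: dict = field(
        default_factory=lambda: {"straight": 1.45, "lesbian": 4.3}
    )
    ksog_group_sds: dict = field(
        default_factory=lambda: {"straight": 0.55, "lesbian": 0.55}
    )
    ksog_cell_sd: float = 0.8
    n_ksog_missing_lesbian: int = 4

    def __post_init__(self) -> None:
        if self.n_straight < 2 or self.n_lesbian < 2:
            raise ValueError("need at least 2 participants per group")
        for name in (
            "long_latency_rate",
            "fast_responder_rate",
            "fast_responder_trial_rate",
            "practice_fail_rate",
            "fast_timeout_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("participant_sd", "residual_log_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.fast_p0 <= self.fast_pinf <= 1.0:
            raise ValueError("need 0 < fast_p0 <= fast_pinf <= 1")

    @classmethod
    def default(cls) -> "GeneratorConfig":
        """The calibrated study-condition defaults from ``defaults.yaml``."""
        ref = importlib.resources.files("irapfast") / "defaults.yaml"
        return cls(**yaml.safe_load(ref.read_text()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def null(self) -> "GeneratorConfig":
        """Copy with zero group effects: no incoherence increments and
        identical learning rates everywhere (downstream AUCs ~ 0.5)."""
        kappa = float(
            np.mean([k for d in self.fast_learn_rate.values() for k in d.values()])
        )
        return dataclasses.replace(
            self,
            irap_effect_matrix={o: [0.0] * 4 for o in _ORIENTATIONS},
            fast_learn_rate={o: {r: kappa for r in _RULES} for o in _ORIENTATIONS},
            ksog_group_means={o: 3.5 for o in _ORIENTATIONS},
        )


@dataclass
class Cohort:
    participants: pd.DataFrame
    irap_trials: pd.DataFrame
    fast_trials: pd.DataFrame
    ksog_cells: pd.DataFrame


def _incoherent_rule(orientation: str) -> str:
    return (
        BlockRule.LESBIAN.value
        if orientation == Orientation.STRAIGHT.value
        else BlockRule.STRAIGHT.value
    )


def irap_latency_model(
    config: GeneratorConfig,
    orientation: str,
    intercept: float,
    effect_shift: float,
    block_rule: str,
    trial_types: np.ndarray,
    rng: np.random.Generator,
    fast_responder: bool = False,
) -> np.ndarray:
    """Draw one block's latencies (ms) for the given trial-type sequence."""
    n = len(trial_types)
    mu = config.base_log_latency + intercept
    log_lat = mu + rng.normal(0.0, config.residual_log_sd, size=n)
    if block_rule == _incoherent_rule(orientation):
        inc = np.asarray(config.irap_effect_matrix[orientation], dtype=float)
        log_lat += inc[trial_types - 1] + effect_shift
    lat = np.exp(log_lat)
    long_mask = rng.random(n) < config.long_latency_rate
    lat[long_mask] = rng.uniform(10_001.0, 14_000.0, size=int(long_mask.sum()))
    if fast_responder:
        fr_mask = rng.random(n) < config.fast_responder_trial_rate
        lat[fr_mask] = rng.uniform(120.0, 299.0, size=int(fr_mask.sum()))
    return np.clip(lat, 1.0, None)


def _block_trial_types(rng: np.random.Generator) -> np.ndarray:
    return rng.permutation(np.repeat(np.arange(1, 5), 6))


def _practice_block(
    config, orientation, intercept, shift, rule, intend_pass, rng, rows, pid, pair
):
    tts = _block_trial_types(rng)
    lat = irap_latency_model(config, orientation, intercept, shift, rule, tts, rng)
    if intend_pass:
        # realize the pass outcome: accuracy >= 20/24 and median < 2000 ms
        n_correct = max(20, rng.binomial(24, 0.92))
        med = float(np.median(lat))
        if med >= 2000.0:
            lat *= 1900.0 / med
    else:
        n_correct = min(19, rng.binomial(24, 0.70))
    correct = np.zeros(24, dtype=bool)
    correct[rng.choice(24, size=n_correct, replace=False)] = True
    for i in range(24):
        rows.append(
            (pid, Phase.PRACTICE.value, pair, rule, int(tts[i]),
             float(lat[i]), bool(correct[i]))
        )


def fast_accuracy_model(
    config: GeneratorConfig,
    kappa: float,
    n_trials: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (correct, timeout) for one block under the learning curve."""
    t = np.arange(1, n_trials + 1, dtype=float)
    p = config.fast_pinf - (config.fast_pinf - config.fast_p0) * np.exp(-kappa * t)
    timeout = rng.random(n_trials) < config.fast_timeout_rate
    correct = (rng.random(n_trials) < p) & ~timeout
    return correct, timeout


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> Cohort:
    """Generate a full synthetic cohort, reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_total = config.n_straight + config.n_lesbian
    pids = [f"P{i + 1:03d}" for i in range(n_total)]
    orientations = [Orientation.STRAIGHT.value] * config.n_straight + [
        Orientation.LESBIAN.value
    ] * config.n_lesbian

    irap_rows: list[tuple] = []
    fast_rows: list[tuple] = []
    ksog_rows: list[tuple] = []
    manifest_rows: list[dict] = []

    lesbian_seen = 0
    for pid, orientation in zip(pids, orientations):
        intercept = rng.normal(0.0, config.participant_sd)
        shift = rng.normal(0.0, config.effect_participant_sd[orientation])
        is_fast_responder = rng.random() < config.fast_responder_rate
        start = rng.permutation(_RULES)  # block order within every pair

        # practice pairs: Bernoulli pass per pair, at most three attempts
        passes = rng.random(MAX_PRACTICE_PAIRS) >= config.practice_fail_rate
        n_pairs = int(np.argmax(passes)) + 1 if passes.any() else MAX_PRACTICE_PAIRS
        eligible = bool(passes[:n_pairs].any())
        for pair in range(1, n_pairs + 1):
            intend_pass = bool(passes[pair - 1])
            for rule in start:
                _practice_block(
                    config, orientation, intercept, shift, rule,
                    intend_pass, rng, irap_rows, pid, pair,
                )

        # exactly three test pairs
        for pair in range(1, N_TEST_PAIRS + 1):
            for rule in start:
                tts = _block_trial_types(rng)
                lat = irap_latency_model(
                    config, orientation, intercept, shift, rule, tts, rng,
                    fast_responder=is_fast_responder,
                )
                correct = rng.random(24) < 0.9
                for i in range(24):
                    irap_rows.append(
                        (pid, Phase.TEST.value, pair, rule, int(tts[i]),
                         float(lat[i]), bool(correct[i]))
                    )

        # FAST: one practice block, then the two test blocks in random order
        kappas = config.fast_learn_rate[orientation]
        mean_kappa = float(np.mean(list(kappas.values())))
        stim_p = rng.choice(_STIM_CLASSES, size=FAST_PRACTICE_TRIALS)
        c, to = fast_accuracy_model(config, mean_kappa, FAST_PRACTICE_TRIALS, rng)
        for i in range(FAST_PRACTICE_TRIALS):
            fast_rows.append(
                (pid, Phase.PRACTICE.value, BlockRule.STRAIGHT.value, i + 1,
                 stim_p[i], bool(c[i]), bool(to[i]))
            )
        for rule in rng.permutation(_RULES):
            stim = rng.choice(_STIM_CLASSES, size=FAST_TEST_TRIALS)
            kappa_mult = float(np.exp(rng.normal(0.0, config.fast_kappa_sd)))
            c, to = fast_accuracy_model(
                config, kappas[rule] * kappa_mult, FAST_TEST_TRIALS, rng
            )
            for i in range(FAST_TEST_TRIALS):
                fast_rows.append(
                    (pid, Phase.TEST.value, rule, i + 1, stim[i],
                     bool(c[i]), bool(to[i]))
                )

        # KSOG grid: latent participant mean, integer cells truncated to 1..7
        lesbian_seen += orientation == Orientation.LESBIAN.value
        missing_grid = (
            orientation == Orientation.LESBIAN.value
            and lesbian_seen <= config.n_ksog_missing_lesbian
        )
        latent = rng.normal(
            config.ksog_group_means[orientation], config.ksog_group_sds[orientation]
        )
        cells = np.clip(
            np.round(rng.normal(latent, config.ksog_cell_sd, size=21)), 1, 7
        )
        k = 0
        for item in range(1, KSOG_ITEMS + 1):
            for tf in KSOG_TIMEFRAMES:
                rating = np.nan if missing_grid else float(cells[k])
                ksog_rows.append((pid, item, tf, rating))
                k += 1

        manifest_rows.append(
            {"participant_id": pid, "orientation": orientation,
             "irap_eligible": eligible}
        )

    irap = pd.DataFrame(
        irap_rows,
        columns=[
            "participant_id", "phase", "pair_index", "block_rule",
            "trial_type", "latency_ms", "first_response_correct",
        ],
    )
    fast = pd.DataFrame(
        fast_rows,
        columns=[
            "participant_id", "phase", "block_rule", "trial_index",
            "stimulus_class", "correct", "timeout",
        ],
    )
    ksog = pd.DataFrame(
        ksog_rows, columns=["participant_id", "item", "timeframe", "rating"]
    )
    return Cohort(pd.DataFrame(manifest_rows), irap, fast, ksog)


# ---------------------------------------------------------------------------
# Vectorized replicate helpers (used by calibration checks)


def _slopes_matrix(correct: np.ndarray) -> np.ndarray:
    """OLS slopes of cumulative records, rows = records."""
    y = np.cumsum(correct.astype(float), axis=1)
    n = correct.shape[1]
    t = np.arange(1, n + 1, dtype=float)
    tc = t - t.mean()
    return (y - y.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)


def simulate_fast_slope_differences(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One cohort's FAST slope differences without materializing trial logs.

    Returns (slope_differences, is_lesbian). Statistically identical to
    scoring the generated trial logs; used for large replicate counts.
    """
    t = np.arange(1, FAST_TEST_TRIALS + 1, dtype=float)
    diffs, lesbian = [], []
    for orientation, n in (
        (Orientation.STRAIGHT.value, config.n_straight),
        (Orientation.LESBIAN.value, config.n_lesbian),
    ):
        slopes = {}
        for rule in _RULES:
            mult = np.exp(rng.normal(0.0, config.fast_kappa_sd, size=n))
            kap = config.fast_learn_rate[orientation][rule] * mult
            p = config.fast_pinf - (config.fast_pinf - config.fast_p0) * np.exp(
                -np.outer(kap, t)
            )
            correct = (rng.random((n, FAST_TEST_TRIALS)) < p) & (
                rng.random((n, FAST_TEST_TRIALS)) >= config.fast_timeout_rate
            )
            slopes[rule] = _slopes_matrix(correct)
        diffs.append(
            slopes[BlockRule.STRAIGHT.value] - slopes[BlockRule.LESBIAN.value]
        )
        lesbian.append(np.full(n, orientation == Orientation.LESBIAN.value))
    return np.concatenate(diffs), np.concatenate(lesbian)
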