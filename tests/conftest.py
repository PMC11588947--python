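"""Shared fixtures: hand-built trial logs and a small synthetic cohort."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from irapfast.simulate import GeneratorConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_irap_block(pid, phase, pair, rule, latencies_by_type, correct=True):
    """One 24-trial block; ``latencies_by_type`` maps trial_type -> 6 latencies."""
    rows = []
    for tt in (1, 2, 3, 4):
        for lat in latencies_by_type[tt]:
            rows.append(
                {
                    "participant_id": pid,
                    "phase": phase,
                    "pair_index": pair,
                    "block_rule": rule,
                    "trial_type": tt,
                    "latency_ms": float(lat),
                    "first_response_correct": bool(correct),
                }
            )
    return rows


def constant_block_latencies(value=1000.0):
    return {tt: [value + 10 * i for i in range(6)] for tt in (1, 2, 3, 4)}


def make_participant_irap(pid="P1", lesbian_extra=0.0, rng=None):
    """A fully valid participant log: 1 passing practice pair + 3 test pairs.

    ``lesbian_extra`` is added to every lesbian-block latency so the sign and
    size of the resulting D scores are known by construction.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for rule in ("straight_block", "lesbian_block"):
        lats = {tt: 1000 + rng.integers(0, 500, 6) for tt in (1, 2, 3, 4)}
        rows += make_irap_block(pid, "practice", 1, rule, lats)
    for pair in (1, 2, 3):
        for rule in ("straight_block", "lesbian_block"):
            extra = lesbian_extra if rule == "lesbian_block" else 0.0
            lats = {
                tt: extra + 1000 + rng.integers(0, 500, 6) for tt in (1, 2, 3, 4)
            }
            rows += make_irap_block(pid, "test", pair, rule, lats)
    return pd.DataFrame(rows)


def make_fast_trials(pid="P1", straight_correct=None, lesbian_correct=None):
    """FAST log with a 16-trial practice block and two 50-trial test blocks."""
    rows = []
    for i in range(16):
        rows.append(
            {
                "participant_id": pid, "phase": "practice",
                "block_rule": "straight_block", "trial_index": i + 1,
                "stimulus_class": "male_pic", "correct": i % 2 == 0,
                "timeout": False,
            }
        )
    for rule, pattern in (
        ("straight_block", straight_correct),
        ("lesbian_block", lesbian_correct),
    ):
        pattern = [True] * 50 if pattern is None else list(pattern)
        for i in range(50):
            rows.append(
                {
                    "participant_id": pid, "phase": "test", "block_rule": rule,
                    "trial_index": i + 1, "stimulus_class": "female_pic",
                    "correct": bool(pattern[i]), "timeout": False,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig.default()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    return generate_cohort(default_config, seed=11)
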