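"""ROC curves, tie-corrected AUC, and DeLong variance/comparison tests.

The AUC is the Mann-Whitney pair-count statistic U/(n1*n2) with ties
half-weighted, computed under a declared direction: with direction
``controls_gt_cases`` the AUC is the probability that a randomly chosen
control scores above a randomly chosen case. This makes it numerically
identical to the Vargha-Delaney A and to the r = W/(n1*n2) estimator from
the rank-sum battery on the same inputs.

DeLong's structural-components estimator provides the sampling variance of
an AUC and the covariance of two AUCs measured on the same participants.
Curves measured on *different* participant sets are compared with the two
independent variances and a Welch-style fractional df, so the reference
distribution is a t rather than a normal.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .types import RocReport

CONTROLS_GT_CASES = "controls_gt_cases"
CASES_GT_CONTROLS = "cases_gt_controls"


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)  # True = case
    cases = scores[labels]
    controls = scores[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both classes must be present")
    return controls, cases


def _placements(controls: np.ndarray, cases: np.ndarray):
    """DeLong structural components: per-control and per-case placement values
    for P(control > case) with ties half-weighted."""
    diff = controls[:, None] - cases[None, :]
    gt = (diff > 0) + 0.5 * (diff == 0)
    v_controls = gt.mean(axis=1)
    v_cases = gt.mean(axis=0)
    return v_controls, v_cases


def auc(scores, labels, direction: str = CONTROLS_GT_CASES) -> float:
    """Tie-corrected pair-count AUC under the declared direction."""
    controls, cases = _split(scores, labels)
    v_controls, _ = _placements(controls, cases)
    a = float(v_controls.mean())
    return a if direction == CONTROLS_GT_CASES else 1.0 - a


def roc_curve(scores, labels, direction: str = CONTROLS_GT_CASES) -> RocReport:
    """Full threshold sweep: (specificity, sensitivity) points plus AUC.

    Sensitivity is the true-positive rate for cases; the specificity axis
    runs from 1 down to 0. Under ``controls_gt_cases`` a *low* score calls a
    case; the direction only flips which tail of the score axis is flagged.
    """
    controls, cases = _split(scores, labels)
    s = np.asarray(scores, dtype=float)
    if direction == CASES_GT_CONTROLS:
        s, controls, cases = -s, -controls, -cases
    elif direction != CONTROLS_GT_CASES:
        raise ValueError(f"unknown direction {direction!r}")
    # thresholds: call "case" when score <= c (cases sit low under this direction)
    cuts = np.concatenate([[-np.inf], np.unique(s), [np.inf]])
    sens = np.array([(cases <= c).mean() for c in cuts])
    spec = np.array([(controls > c).mean() for c in cuts])
    order = np.argsort(-spec, kind="stable")
    return RocReport(
        specificity=spec[order],
        sensitivity=sens[order],
        auc=auc(scores, labels, direction),
        direction=direction,
    )


def delong_variance(scores, labels) -> float:
    """Sampling variance of the AUC by DeLong's structural components."""
    controls, cases = _split(scores, labels)
    v_controls, v_cases = _placements(controls, cases)
    m, n = len(controls), len(cases)
    if m < 2 or n < 2:
        raise ValueError("need >=2 observations per class")
    s10 = v_controls.var(ddof=1)
    s01 = v_cases.var(ddof=1)
    return float(s10 / m + s01 / n)


def delong_covariance(scores1, scores2, labels) -> float:
    """Covariance of two AUCs measured on the same labelled participants."""
    c1, k1 = _split(scores1, labels)
    c2, k2 = _split(scores2, labels)
    v1c, v1k = _placements(c1, k1)
    v2c, v2k = _placements(c2, k2)
    m, n = len(c1), len(k1)
    s10 = np.cov(v1c, v2c, ddof=1)[0, 1]
    s01 = np.cov(v1k, v2k, ddof=1)[0, 1]
    return float(s10 / m + s01 / n)


def delong_test_paired(scores1, scores2, labels) -> tuple[float, float, float]:
    """Compare two AUCs on identical participants: z statistic, df=inf, p."""
    a1 = auc(scores1, labels)
    a2 = auc(scores2, labels)
    var = (
        delong_variance(scores1, labels)
        + delong_variance(scores2, labels)
        - 2.0 * delong_covariance(scores1, scores2, labels)
    )
    if var <= 0:
        # identical (or perfectly covarying) curves: the null comparison
        if abs(a1 - a2) < 1e-12:
            return 0.0, math.inf, 1.0
        raise ValueError("degenerate variance in paired AUC comparison")
    z = (a1 - a2) / math.sqrt(var)
    return float(z), math.inf, float(2 * sps.norm.sf(abs(z)))


def delong_test_unpaired(
    scores1, labels1, scores2, labels2
) -> tuple[float, float, float]:
    """Compare two AUCs from different participant sets.

    Uses the two independent DeLong variances with a Welch-Satterthwaite
    fractional df (each variance weighted by its sample size minus one), so
    the statistic is referred to a t distribution.
    """
    a1, a2 = auc(scores1, labels1), auc(scores2, labels2)
    v1 = delong_variance(scores1, labels1)
    v2 = delong_variance(scores2, labels2)
    if v1 + v2 <= 0:
        raise ValueError("degenerate variance in AUC comparison")
    n1 = len(np.asarray(scores1))
    n2 = len(np.asarray(scores2))
    d = (a1 - a2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(d), float(df), float(2 * sps.t.sf(abs(d), df))
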