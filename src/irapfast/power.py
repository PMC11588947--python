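"""Analytic sensitivity (minimal detectable effect) computations.

Power for the two-sample t test comes from the noncentral t distribution
with df = n1 + n2 - 2 and noncentrality d * sqrt(n1*n2/(n1+n2)); for the
within-between interaction of a mixed ANOVA it comes from the noncentral F
with df1 = (g-1)(m-1)*eps, df2 = (N-g)(m-1)*eps and noncentrality
lambda = f^2 * N * m * eps / (1 - rho) -- the "as in SPSS" convention where
rho is the correlation among the repeated measures and eps the
nonsphericity correction. The minimal detectable effect is the smallest
effect reaching the target power, found by bisection on the (monotone)
power function.
"""

from __future__ import annotations

import math

from scipy import optimize
from scipy import stats as sps

_BRACKET_HI = 10.0
_XTOL = 1e-8


def power_two_sample_t(
    d: float, n1: int, n2: int, alpha: float = 0.05, tails: int = 2
) -> float:
    """Power of the (two-tailed by default) two-sample t test at effect d."""
    df = n1 + n2 - 2
    nc = d * math.sqrt(n1 * n2 / (n1 + n2))
    if tails == 2:
        crit = sps.t.ppf(1 - alpha / 2, df)
        p = sps.nct.sf(crit, df, nc) + sps.nct.cdf(-crit, df, nc)
    else:
        crit = sps.t.ppf(1 - alpha, df)
        p = sps.nct.sf(crit, df, nc)
    if math.isnan(p):  # scipy's nct overflows at extreme noncentrality
        p = sps.norm.sf(crit - nc)
    return float(p)


def mde_two_sample_t(
    n1: int, n2: int, alpha: float = 0.05, power: float = 0.80, tails: int = 2
) -> float:
    """Smallest Cohen's d whose two-sample t test reaches the target power."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")

    def gap(d):
        return power_two_sample_t(d, n1, n2, alpha, tails) - power

    if gap(_BRACKET_HI) < 0:
        raise ValueError("target power unattainable at these sample sizes")
    return float(optimize.brentq(gap, 0.0, _BRACKET_HI, xtol=_XTOL))


def power_within_between_interaction(
    f: float,
    n_total: int,
    n_groups: int,
    n_measures: int,
    rho: float = 0.5,
    epsilon: float = 1.0,
    alpha: float = 0.05,
) -> float:
    """Power of the group x measure interaction F test at effect size f."""
    if not 0 <= rho < 1 or not 0 < epsilon <= 1:
        raise ValueError("need rho in [0,1) and epsilon in (0,1]")
    df1 = (n_groups - 1) * (n_measures - 1) * epsilon
    df2 = (n_total - n_groups) * (n_measures - 1) * epsilon
    lam = f**2 * n_total * n_measures * epsilon / (1.0 - rho)
    crit = sps.f.ppf(1 - alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def mde_within_between_interaction(
    n_total: int,
    n_groups: int,
    n_measures: int,
    rho: float = 0.5,
    epsilon: float = 1.0,
    alpha: float = 0.05,
    power: float = 0.80,
) -> float:
    """Smallest Cohen's f whose interaction F test reaches the target power."""
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")

    def gap(f):
        return (
            power_within_between_interaction(
                f, n_total, n_groups, n_measures, rho, epsilon, alpha
            )
            - power
        )

    if gap(_BRACKET_HI) < 0:
        raise ValueError("target power unattainable at this design size")
    return float(optimize.brentq(gap, 0.0, _BRACKET_HI, xtol=_XTOL))


def f_to_eta2p(f: float) -> float:
    """Partial eta squared from Cohen's f: f^2 / (1 + f^2)."""
    if f < 0:
        raise ValueError("f must be >= 0")
    return f**2 / (1.0 + f**2)


def eta2p_to_f(eta2p: float) -> float:
    """Cohen's f from partial eta squared: sqrt(eta2p / (1 - eta2p))."""
    if not 0 <= eta2p < 1:
        raise ValueError("eta2p must lie in [0, 1)")
    return math.sqrt(eta2p / (1.0 - eta2p))
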