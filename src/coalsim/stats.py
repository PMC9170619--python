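"""Outcome statistics for coalition frequency tables.

Covers the quantities typically reported for triadic coalition studies:
Cohen's w against an expected distribution (default: uniform over the
coalitions that can form), the chi-square goodness-of-fit test, its
power and minimum detectable effect size via the noncentral chi-square
distribution, odds ratios between two proportions, and Cohen's d from
summary statistics.

Values are never rounded here; display rounding happens at the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .game import GameError


class StatsError(GameError):
    pass


@dataclass(frozen=True)
class FrequencyTable:
    """Observed coalition counts against expected proportions.

    ``observed`` may be fractional when built from printed percentages
    rather than raw counts; it must still sum to ``n``.
    """

    labels: tuple[str, ...]
    observed: tuple[float, ...]
    n: float
    expected_p: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.labels)
        if k < 2:
            raise StatsError("need at least 2 categories")
        if len(self.observed) != k or len(self.expected_p) != k:
            raise StatsError("labels, observed and expected lengths differ")
        if any(c < 0 for c in self.observed):
            raise StatsError("negative count")
        if not np.isclose(sum(self.observed), self.n):
            raise StatsError("counts do not sum to n")
        if not np.isclose(sum(self.expected_p), 1.0):
            raise StatsError("expected proportions do not sum to 1")

    @property
    def observed_p(self) -> tuple[float, ...]:
        return tuple(c / self.n for c in self.observed)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, float],
        expected_p: Mapping[str, float] | None = None,
    ) -> "FrequencyTable":
        labels = tuple(counts)
        n = float(sum(counts.values()))
        if expected_p is None:
            exp = tuple(1.0 / len(labels) for _ in labels)
        else:
            if set(expected_p) != set(labels):
                raise StatsError("expected proportions label mismatch")
            exp = tuple(float(expected_p[lab]) for lab in labels)
        return cls(
            labels=labels,
            observed=tuple(float(c) for c in counts.values()),
            n=n,
            expected_p=exp,
        )

    @classmethod
    def from_proportions(
        cls,
        proportions: Mapping[str, float],
        n: float,
        expected_p: Mapping[str, float] | None = None,
    ) -> "FrequencyTable":
        """Build from printed proportions (e.g. 0.67/0.29/0.04) at size n."""
        return cls.from_counts(
            {lab: p * n for lab, p in proportions.items()},
            expected_p=expected_p,
        )


def cohens_w(table: FrequencyTable) -> float:
    """Effect size w = sqrt(sum_i (p_i - pi_i)^2 / pi_i)."""
    if any(pi <= 0 for pi in table.expected_p):
        raise StatsError("expected proportions must all be positive")
    p = np.asarray(table.observed_p)
    pi = np.asarray(table.expected_p)
    return float(np.sqrt(np.sum((p - pi) ** 2 / pi)))


def chisq_gof(table: FrequencyTable) -> tuple[float, int, float]:
    """Goodness-of-fit statistic n*w^2, df = k-1, and upper-tail p."""
    w = cohens_w(table)
    statistic = table.n * w * w
    df = len(table.labels) - 1
    p = float(sps.chi2.sf(statistic, df))
    return statistic, df, p


def gof_power(w: float, n: float, df: int, alpha: float) -> float:
    """Power of the chi-square GOF test at effect w and sample size n.

    power = P[ chi2_noncentral(df, lambda = n*w^2) > chi2_crit(df, 1-alpha) ].
    At w = 0 this is exactly alpha.
    """
    _check_power_args(n, df, alpha)
    if w < 0:
        raise StatsError("w must be >= 0")
    crit = sps.chi2.ppf(1.0 - alpha, df)
    lam = n * w * w
    if lam == 0:
        return float(alpha)
    return float(sps.ncx2.sf(crit, df, lam))


#: Bisection bracket on the noncentrality parameter.
_LAMBDA_LO, _LAMBDA_HI = 1e-6, 1e3


def min_detectable_w(power: float, n: float, df: int, alpha: float) -> float:
    """Smallest w the GOF test detects with the given power (MDES).

    Solves the power equation for the noncentrality lambda by bisection
    on [1e-6, 1e3] to 1e-10 and returns sqrt(lambda / n); exact inverse
    of :func:`gof_power`.
    """
    _check_power_args(n, df, alpha)
    if not 0.0 < power < 1.0:
        raise StatsError("power must be in (0, 1)")
    crit = sps.chi2.ppf(1.0 - alpha, df)

    def gap(lam: float) -> float:
        return sps.ncx2.sf(crit, df, lam) - power

    lo, hi = _LAMBDA_LO, _LAMBDA_HI
    if gap(lo) > 0 or gap(hi) < 0:
        raise StatsError(
            f"no noncentrality in [{lo}, {hi}] reaches power {power}"
        )
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if gap(mid) < 0:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    return float(np.sqrt(lam / n))


def _check_power_args(n: float, df: int, alpha: float) -> None:
    if n < 1:
        raise StatsError("n must be >= 1")
    if df < 1:
        raise StatsError("df must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise StatsError("alpha must be in (0, 1)")


def odds_ratio(p1: float, p2: float) -> float:
    """OR = [p1/(1-p1)] / [p2/(1-p2)] for two event proportions."""
    for p in (p1, p2):
        if not 0.0 < p < 1.0:
            raise StatsError("proportions must be strictly between 0 and 1")
    return (p1 / (1.0 - p1)) / (p2 / (1.0 - p2))


def odds_ratio_counts(k1: float, n1: float, k2: float, n2: float) -> float:
    """Count-based overload: OR from events/totals in two groups."""
    if n1 <= 0 or n2 <= 0:
        raise StatsError("group sizes must be positive")
    return odds_ratio(k1 / n1, k2 / n2)


def cohens_d(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> float:
    """Standardized mean difference using the pooled standard deviation."""
    if sd1 <= 0 or sd2 <= 0:
        raise StatsError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise StatsError("group sizes must be >= 2")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise StatsError("non-positive pooled variance")
    return (m1 - m2) / float(np.sqrt(pooled_var))


@dataclass(frozen=True)
class EffectSummary:
    """Derived statistics for one frequency table."""

    w: float
    statistic: float
    df: int
    p_value: float
    alpha: float
    power_at_observed_w: float
    target_power: float
    min_detectable_w: float

    def as_dict(self) -> dict:
        return {
            "w": self.w,
            "chi2": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "power_at_observed_w": self.power_at_observed_w,
            "target_power": self.target_power,
            "min_detectable_w": self.min_detectable_w,
        }


def summarize(
    table: FrequencyTable, alpha: float = 0.05, target_power: float = 0.80
) -> EffectSummary:
    """Full effect summary: w, GOF test, power at observed w, and MDES."""
    w = cohens_w(table)
    statistic, df, p = chisq_gof(table)
    return EffectSummary(
        w=w,
        statistic=statistic,
        df=df,
        p_value=p,
        alpha=alpha,
        power_at_observed_w=gof_power(w, table.n, df, alpha),
        target_power=target_power,
        min_detectable_w=min_detectable_w(target_power, table.n, df, alpha),
    )
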