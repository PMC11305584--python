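"""Standard errors and p-values reconstructed from printed CIs, and binomial intervals.

Ratio effect measures (OR, RR, HR, IRR) are analysed on the natural-log
scale, where a published 95% CI implies a standard error

    SE = (ln hi - ln lo) / 3.92

and a two-sided p-value via z = ln(point)/SE under the standard normal.
The divisor is kept literally at 3.92 (twice the conventional 1.96) rather
than 2*Phi^{-1}(0.975); the difference is far below the rounding of any
printed interval.

Binomial proportions (replication rates, ORR estimates) get their intervals
from statsmodels: Wilson score, Wald (normal approximation, truncated to
[0, 1]) and Clopper-Pearson exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .core_data import EffectEstimate, EffectMeasure, ValidationError

__all__ = [
    "LogScaleSummary",
    "UnsupportedMeasureError",
    "DegenerateIntervalError",
    "UndefinedRateError",
    "ZeroCellError",
    "CI_Z_WIDTH",
    "se_from_ci",
    "p_from_estimate",
    "wilson_interval",
    "wald_interval",
    "clopper_pearson",
    "orr_from_counts",
    "ratio_from_2x2",
]

#: Width of a 95% CI in standard-error units on the log scale (2 x 1.96).
CI_Z_WIDTH = 3.92


class UnsupportedMeasureError(ValueError):
    """Operation defined for ratio measures only."""


class DegenerateIntervalError(ValueError):
    """CI has zero width; no standard error can be reconstructed."""


class UndefinedRateError(ValueError):
    """A proportion over zero trials is undefined."""


class ZeroCellError(ValueError):
    """A 2x2 cell needed by the SE formula is zero."""


@dataclass(frozen=True)
class LogScaleSummary:
    """Log-scale point estimate, reconstructed SE, z statistic and p-value."""

    log_point: float
    se: float
    z: float
    p: float


def _require_ratio(estimate: EffectEstimate) -> None:
    if not estimate.measure.is_ratio:
        raise UnsupportedMeasureError(
            "ORR is a proportion; log-scale SE reconstruction applies to ratio measures only"
        )


def se_from_ci(estimate: EffectEstimate) -> float:
    """Standard error of the log effect implied by a printed 95% CI.

    Returns ``(ln hi - ln lo) / 3.92``, strictly positive whenever the
    interval has positive width.
    """
    _require_ratio(estimate)
    if estimate.lo == estimate.hi:
        raise DegenerateIntervalError(
            f"interval [{estimate.lo}, {estimate.hi}] has zero width"
        )
    return (math.log(estimate.hi) - math.log(estimate.lo)) / CI_Z_WIDTH


def p_from_estimate(estimate: EffectEstimate) -> LogScaleSummary:
    """Two-sided normal-approximation p-value reconstructed from a printed CI.

    The published point estimate and CI bounds are all the information the
    analysis has, so the test statistic is z = ln(point)/SE with SE from
    :func:`se_from_ci`; p < 0.05 if and only if the 95% CI excludes 1, up to
    the rounding of the printed bounds.
    """
    se = se_from_ci(estimate)
    log_point = math.log(estimate.point)
    z = log_point / se
    p = 2.0 * stats.norm.sf(abs(z))
    return LogScaleSummary(log_point=log_point, se=se, z=z, p=p)


def _check_counts(successes: int, n: int) -> None:
    if n == 0:
        raise UndefinedRateError("a proportion over n = 0 trials is undefined")
    if not (0 <= successes <= n):
        raise ValueError(f"need 0 <= successes <= n, got {successes}/{n}")


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    _check_counts(successes, n)
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
    return (float(lo), float(hi))


def wald_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald (normal-approximation) interval, truncated to [0, 1]."""
    _check_counts(successes, n)
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="normal")
    return (max(0.0, float(lo)), min(1.0, float(hi)))


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact interval from beta quantiles.

    Guarantees coverage >= level for every true proportion; the lower bound
    is exactly 0 when successes = 0 and the upper exactly 1 when
    successes = n.
    """
    _check_counts(successes, n)
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="beta")
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return (lo, hi)


def orr_from_counts(responders: int, n: int) -> EffectEstimate:
    """Objective response rate with an exact 95% Clopper-Pearson interval."""
    _check_counts(responders, n)
    lo, hi = clopper_pearson(responders, n, 0.95)
    return EffectEstimate(
        measure=EffectMeasure.ORR, point=responders / n, lo=lo, hi=hi, level=0.95
    )


def ratio_from_2x2(
    events_a: int,
    total_a: int,
    events_b: int,
    total_b: int,
    target: EffectMeasure,
) -> EffectEstimate:
    """OR or RR with log-scale Wald CI from a 2x2 table.

    Group a is the intervention arm, group b the comparator. Standard SE
    formulas: OR uses sqrt(1/a + 1/b + 1/c + 1/d) over the four cells; RR
    uses sqrt(1/a - 1/n1 + 1/c - 1/n2). No continuity correction is applied;
    a zero cell that makes the SE undefined raises :class:`ZeroCellError`
    (callers wanting a 0.5 correction must add it explicitly).
    """
    if target not in (EffectMeasure.OR, EffectMeasure.RR):
        raise UnsupportedMeasureError(f"2x2 conversion targets OR or RR, not {target.value}")
    if total_a < 1 or total_b < 1:
        raise ValueError("arm totals must be >= 1")
    if not (0 <= events_a <= total_a and 0 <= events_b <= total_b):
        raise ValueError("events must lie between 0 and the arm total")

    a, c = events_a, events_b
    b, d = total_a - events_a, total_b - events_b
    if target is EffectMeasure.OR:
        if min(a, b, c, d) == 0:
            raise ZeroCellError("zero cell in 2x2 table; OR standard error undefined")
        point = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    else:
        if a == 0 or c == 0:
            raise ZeroCellError("zero event count; RR standard error undefined")
        point = (a / total_a) / (c / total_b)
        se = math.sqrt(1 / a - 1 / total_a + 1 / c - 1 / total_b)

    z = stats.norm.ppf(0.975)
    log_point = math.log(point)
    return EffectEstimate(
        measure=target,
        point=point,
        lo=math.exp(log_point - z * se),
        hi=math.exp(log_point + z * se),
        level=0.95,
    )
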