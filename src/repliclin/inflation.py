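"""Effect-size inflation ratios, coining and order-inversion transforms, summaries.

The inflation ratio of a pair is oriented so that values above 1 mean the
earlier (highly cited) study showed the stronger effect:

* unfavorable outcomes (death, progression; effectiveness grows as the
  measure shrinks): ratio = replication / original;
* favorable outcomes (response, neurologic improvement): ratio =
  original / replication.

Two optional transforms mirror the published sensitivity analyses.
**Order inversion** reciprocates the ratio for pairs where most of the
replication evidence predates the highly cited study, so that study is the
de-facto replication. **Coining** converts favorable outcomes to unfavorable
ones (1-ORR, 1/OR, complementary-event RR from counts) so every pair shares
one orientation without ratio flipping.

Summaries average natural logs of the ratios, attach a t-based CI and a
one-sample t-test against zero (no systematic inflation), and exponentiate
back to the ratio scale — the geometric mean.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_data import Direction, EffectEstimate, EffectMeasure, StudyPair
from .interval_stats import ratio_from_2x2

__all__ = [
    "InflationRecord",
    "InflationSummary",
    "MissingDataError",
    "UndefinedRatioError",
    "pair_ratio",
    "coin_estimate",
    "coin_pair",
    "summarize_inflation",
]

logger = logging.getLogger(__name__)


class UndefinedRatioError(ValueError):
    """A zero point estimate admits no ratio."""


class MissingDataError(ValueError):
    """Coining an RR requires the per-arm counts of the complementary outcome."""


@dataclass(frozen=True)
class InflationRecord:
    """One pair's inflation ratio and the transformations applied to it."""

    pair_id: str
    ratio: float
    log_ratio: float
    inverted: bool
    coined: bool


@dataclass(frozen=True)
class InflationSummary:
    """Geometric-mean ratio with back-transformed t-interval and t-test p-value."""

    mean_ratio: float
    ci: Optional[tuple[float, float]]
    p: Optional[float]
    n: int
    subgroup: str = "all"


def pair_ratio(pair: StudyPair, apply_inversion: bool = True, coined: bool = False) -> InflationRecord:
    """Inflation ratio of one pair on the effect-measure scale.

    The base ratio is replication/original for unfavorable outcomes and
    original/replication for favorable ones; with ``apply_inversion`` the
    ratio is reciprocated for pairs flagged ``order_inverted``. ``coined``
    only labels the record (use :func:`coin_pair` first to transform the
    estimates).
    """
    if pair.original.point == 0 or pair.replication.point == 0:
        raise UndefinedRatioError(f"pair {pair.pair_id!r}: zero point estimate")
    if pair.direction is Direction.UNFAVORABLE:
        ratio = pair.replication.point / pair.original.point
    else:
        ratio = pair.original.point / pair.replication.point
    inverted = apply_inversion and pair.order_inverted
    if inverted:
        ratio = 1.0 / ratio
    return InflationRecord(
        pair_id=pair.pair_id,
        ratio=ratio,
        log_ratio=math.log(ratio),
        inverted=inverted,
        coined=coined,
    )


def coin_estimate(
    estimate: EffectEstimate,
    counts: Optional[tuple[int, int, int, int]] = None,
) -> EffectEstimate:
    """Convert a favorable-outcome estimate to its unfavorable complement.

    ORR becomes the non-response rate 1 - ORR (interval reflected); OR is
    inverted to 1/OR (bounds swapped and reciprocated); RR requires the 2x2
    counts ``(events_a, total_a, events_b, total_b)`` so the complementary
    outcome's RR can be recomputed from data.
    """
    m = estimate.measure
    if m is EffectMeasure.ORR:
        return EffectEstimate(
            measure=m,
            point=1.0 - estimate.point,
            lo=1.0 - estimate.hi,
            hi=1.0 - estimate.lo,
            level=estimate.level,
        )
    if m is EffectMeasure.OR:
        return EffectEstimate(
            measure=m,
            point=1.0 / estimate.point,
            lo=1.0 / estimate.hi,
            hi=1.0 / estimate.lo,
            level=estimate.level,
        )
    if m is EffectMeasure.RR:
        if counts is None:
            raise MissingDataError(
                "coining an RR needs per-arm counts for the complementary outcome"
            )
        events_a, total_a, events_b, total_b = counts
        return ratio_from_2x2(
            total_a - events_a, total_a, total_b - events_b, total_b, EffectMeasure.RR
        )
    raise MissingDataError(f"no coining rule for measure {m.value}")


def coin_pair(
    pair: StudyPair,
    original_counts: Optional[tuple[int, int, int, int]] = None,
    replication_counts: Optional[tuple[int, int, int, int]] = None,
) -> StudyPair:
    """Coin both sides of a favorable pair; unfavorable pairs pass through.

    Raises :class:`MissingDataError` for favorable RR pairs without counts;
    callers typically log and exclude those from coined analyses.
    """
    if pair.direction is Direction.UNFAVORABLE:
        return pair
    return dataclasses.replace(
        pair,
        original=coin_estimate(pair.original, original_counts),
        replication=coin_estimate(pair.replication, replication_counts),
        direction=Direction.UNFAVORABLE,
    )


def summarize_inflation(
    records: Sequence[InflationRecord], subgroup: str = "all"
) -> InflationSummary:
    """Geometric-mean inflation ratio with 95% t-interval and one-sample t-test.

    The mean and interval are computed on natural logs and exponentiated
    back; the p-value tests the mean log ratio against 0. With a single
    record the CI and p are undefined; a zero-variance set yields p = 1 with
    a warning (the degenerate limit of the t-test).
    """
    n = len(records)
    if n == 0:
        raise ValueError("cannot summarize zero inflation records")
    logs = np.array([r.log_ratio for r in records], dtype=float)
    mean_log = float(logs.mean())
    mean_ratio = math.exp(mean_log)
    if n == 1:
        return InflationSummary(mean_ratio=mean_ratio, ci=None, p=None, n=1, subgroup=subgroup)

    sd = float(logs.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "zero variance among log inflation ratios; t-test degenerate, p set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return InflationSummary(
            mean_ratio=mean_ratio, ci=(mean_ratio, mean_ratio), p=1.0, n=n, subgroup=subgroup
        )

    half = stats.t.ppf(0.975, df=n - 1) * sd / math.sqrt(n)
    p = float(stats.ttest_1samp(logs, popmean=0.0).pvalue)
    return InflationSummary(
        mean_ratio=mean_ratio,
        ci=(math.exp(mean_log - half), math.exp(mean_log + half)),
        p=p,
        n=n,
        subgroup=subgroup,
    )
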