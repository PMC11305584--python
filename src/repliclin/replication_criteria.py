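"""Replication-success criteria, per-pair verdicts and criterion-level rates.

Two primary criteria define replication success for a study pair:

* **significance-direction concordance** — the replication reaches p < 0.05
  (reconstructed from its printed CI) with its effect on the same side of the
  null as the original; applied only when the original was a statistically
  significant controlled trial;
* **CI overlap** — the 95% CIs of the two estimates are non-disjoint
  (closed intervals: a shared endpoint counts as overlap).

The aggregate criterion conjoins the two, but never counts an inapplicable
significance comparison (phase-1 or initially non-significant originals) as
a failure — those pairs are judged by overlap alone. Two containment
criteria (each study's point inside the other's CI) and a sensitivity
variant that scores non-significant originals as well are also provided.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .core_data import PairTable, Significance, StudyPair, ValidationError
from .interval_stats import p_from_estimate, wald_interval, wilson_interval

__all__ = [
    "TriState",
    "Criterion",
    "ReplicationVerdict",
    "CriterionRate",
    "intervals_overlap",
    "point_in_interval",
    "sig_concordant",
    "assess_pair",
    "criterion_rates",
]


class TriState(enum.Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_APPLICABLE = "not_applicable"


class Criterion(enum.Enum):
    SIGNIFICANCE = "significance"
    OVERLAP = "overlap"
    AGGREGATE = "aggregate"
    SIGNIFICANCE_WITH_NEGATIVES = "significance_with_negatives"
    FORWARD_CONTAINMENT = "forward_containment"
    REVERSE_CONTAINMENT = "reverse_containment"


@dataclass(frozen=True)
class ReplicationVerdict:
    """Per-pair outcome of every replication criterion.

    ``forward_containment`` is the replication point inside the original CI,
    ``reverse_containment`` the original point inside the replication CI.
    ``aggregate`` is the primary-outcome criterion:
    overlap AND (significance concordance != fail).
    """

    pair_id: str
    sig_concordant: TriState
    ci_overlap: bool
    forward_containment: bool
    reverse_containment: bool
    aggregate: bool


@dataclass(frozen=True)
class CriterionRate:
    """A criterion's success count, rate and binomial CI over its denominator."""

    criterion: Criterion
    numerator: int
    denominator: int
    rate: Optional[float]
    ci: Optional[tuple[float, float]]
    interval_method: str = "wilson"

    @property
    def undefined(self) -> bool:
        return self.denominator == 0


def intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True iff the closed intervals share at least one point."""
    (a_lo, a_hi), (b_lo, b_hi) = a, b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("interval bounds out of order")
    return max(a_lo, b_lo) <= min(a_hi, b_hi)


def point_in_interval(point: float, iv: tuple[float, float]) -> bool:
    """True iff lo <= point <= hi (closed interval)."""
    lo, hi = iv
    if lo > hi:
        raise ValueError("interval bounds out of order")
    return lo <= point <= hi


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def sig_concordant(
    pair: StudyPair, alpha: float = 0.05, include_negatives: bool = False
) -> TriState:
    """Significance-direction concordance of a replication with its original.

    Not applicable when the original reported no test (phase-1/ORR pairs),
    or when it was non-significant and ``include_negatives`` is False.
    With ``include_negatives``, an initially non-significant original is
    concordant only if its replication also fails to reach significance.
    """
    if pair.original_significant is Significance.NOT_APPLICABLE:
        return TriState.NOT_APPLICABLE
    if not pair.measure.is_ratio:
        raise ValidationError(
            f"pair {pair.pair_id!r}: an ORR pair cannot carry a significance flag"
        )
    if pair.original_significant is Significance.NONSIGNIFICANT and not include_negatives:
        return TriState.NOT_APPLICABLE

    rep = p_from_estimate(pair.replication)
    rep_significant = rep.p < alpha
    if pair.original_significant is Significance.NONSIGNIFICANT:
        # Sensitivity rule: concordant nulls pass, a newly significant
        # replication counts as discordant.
        return TriState.FAIL if rep_significant else TriState.PASS

    same_direction = _sign(rep.log_point) == _sign(math.log(pair.original.point))
    return TriState.PASS if (rep_significant and same_direction) else TriState.FAIL


def assess_pair(pair: StudyPair, alpha: float = 0.05) -> ReplicationVerdict:
    """Evaluate every replication criterion for one pair."""
    overlap = intervals_overlap(pair.original.interval, pair.replication.interval)
    concordance = sig_concordant(pair, alpha=alpha, include_negatives=False)
    return ReplicationVerdict(
        pair_id=pair.pair_id,
        sig_concordant=concordance,
        ci_overlap=overlap,
        forward_containment=point_in_interval(pair.replication.point, pair.original.interval),
        reverse_containment=point_in_interval(pair.original.point, pair.replication.interval),
        aggregate=overlap and concordance is not TriState.FAIL,
    )


_RATE_INTERVALS = {"wilson": wilson_interval, "wald": wald_interval}


def _rate(
    criterion: Criterion, numerator: int, denominator: int, interval: str
) -> CriterionRate:
    if denominator == 0:
        return CriterionRate(criterion, 0, 0, None, None, interval)
    ci = _RATE_INTERVALS[interval](numerator, denominator, 0.95)
    return CriterionRate(criterion, numerator, denominator, numerator / denominator, ci, interval)


def criterion_rates(
    verdicts: Sequence[ReplicationVerdict],
    pairs: PairTable,
    alpha: float = 0.05,
    interval: str = "wilson",
) -> list[CriterionRate]:
    """Success rates for all six criteria with binomial CIs.

    Denominators follow the published analysis: the significance criterion
    counts only pairs whose original was significant; its sensitivity variant
    adds the non-significant originals; every other criterion runs over all
    pairs. ``interval`` selects the rate-CI estimator ("wilson" default,
    "wald" available); an empty denominator yields an undefined rate rather
    than an exception.
    """
    if interval not in _RATE_INTERVALS:
        raise ValueError(f"unknown interval estimator {interval!r}")
    by_id = {p.pair_id: p for p in pairs}
    if sorted(by_id) != sorted(v.pair_id for v in verdicts):
        raise ValueError("verdicts do not correspond 1:1 to pairs")

    sig_pairs = [v for v in verdicts if by_id[v.pair_id].original_significant is Significance.SIGNIFICANT]
    with_neg = [
        sig_concordant(by_id[v.pair_id], alpha=alpha, include_negatives=True)
        for v in verdicts
        if by_id[v.pair_id].original_significant is not Significance.NOT_APPLICABLE
    ]
    n_all = len(verdicts)
    return [
        _rate(
            Criterion.SIGNIFICANCE,
            sum(v.sig_concordant is TriState.PASS for v in sig_pairs),
            len(sig_pairs),
            interval,
        ),
        _rate(Criterion.OVERLAP, sum(v.ci_overlap for v in verdicts), n_all, interval),
        _rate(Criterion.AGGREGATE, sum(v.aggregate for v in verdicts), n_all, interval),
        _rate(
            Criterion.SIGNIFICANCE_WITH_NEGATIVES,
            sum(s is TriState.PASS for s in with_neg),
            len(with_neg),
            interval,
        ),
        _rate(
            Criterion.FORWARD_CONTAINMENT,
            sum(v.forward_containment for v in verdicts),
            n_all,
            interval,
        ),
        _rate(
            Criterion.REVERSE_CONTAINMENT,
            sum(v.reverse_containment for v in verdicts),
            n_all,
            interval,
        ),
    ]
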