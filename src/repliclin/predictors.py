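"""Comparisons of replicated versus contradicted pairs over their annotations.

For a chosen replication criterion, pairs are split into replicated and
contradicted groups; categorical annotations (study design, intervention
type) are compared with Fisher's exact test and continuous ones (citations
per year, original sample size, original p-value) with the Mann-Whitney U
test. Pairs missing a continuous value are dropped from that comparison
only. With few contradicted studies these tests have little power — the
summaries (per-category fractions, medians with IQR) are the informative
output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_data import Design, InterventionType, PairTable, Significance, StudyPair
from .replication_criteria import Criterion, ReplicationVerdict, TriState

__all__ = [
    "PredictorComparison",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "compare_predictors",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictorComparison:
    """One predictor-vs-criterion comparison.

    ``group_summary`` holds medians with IQR per group for continuous
    predictors, or per-category replicated/contradicted fractions for
    categorical ones. ``p`` is None when a group was empty (comparison
    undefined).
    """

    predictor: str
    criterion: Criterion
    test: str  # "fisher_exact" | "mann_whitney"
    group_summary: dict
    p: Optional[float]

    @property
    def undefined(self) -> bool:
        return self.p is None


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the convention of summing hypergeometric probabilities of all
    tables (with fixed margins) no more probable than the observed one.
    A zero margin makes the table degenerate; p = 1 is returned with a
    warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    if t.sum() == 0:
        raise ValueError("at least one margin must be nonzero")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; Fisher p = 1", RuntimeWarning, stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact by enumeration when the combined sample has at most 10 tie-free
    values; otherwise the normal approximation with tie correction (no
    continuity correction, so identical samples give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and pooled.size <= 10:
        method = "exact"
        use_continuity = True  # ignored on the exact path
    else:
        method = "asymptotic"
        use_continuity = False
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=use_continuity
    )
    return float(res.pvalue)


def _passes(pair: StudyPair, verdict: ReplicationVerdict, criterion: Criterion) -> Optional[bool]:
    """Whether the pair counts as replicated under the criterion, or None if
    it is outside the criterion's denominator."""
    if criterion is Criterion.SIGNIFICANCE:
        if pair.original_significant is not Significance.SIGNIFICANT:
            return None
        return verdict.sig_concordant is TriState.PASS
    if criterion is Criterion.OVERLAP:
        return verdict.ci_overlap
    if criterion is Criterion.AGGREGATE:
        return verdict.aggregate
    raise ValueError(f"unsupported predictor criterion {criterion}")


def _median_iqr(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "iqr": [float(q1), float(q3)], "n": int(values.size)}


_CONTINUOUS = {
    "citations_per_year": lambda p: p.citations_per_year,
    "original_n": lambda p: p.original_n,
    "original_p": lambda p: p.original_p,
}

_CATEGORICAL = {
    "original_design": lambda p: p.original_design is Design.RCT,
    "intervention_type": lambda p: p.intervention_type is InterventionType.PHARMACOLOGICAL,
}


def compare_predictors(
    pairs: PairTable,
    verdicts: Sequence[ReplicationVerdict],
    criterion: Criterion,
) -> list[PredictorComparison]:
    """All predictor comparisons for one replication criterion.

    Categorical predictors yield a replicated-vs-contradicted 2x2 per binary
    annotation (Fisher exact); continuous predictors yield a two-group rank
    comparison (Mann-Whitney) with per-group medians and IQRs. A comparison
    with an empty replicated or contradicted group is flagged undefined
    (p = None); pairs with missing continuous values are skipped with a log
    entry.
    """
    by_id = {p.pair_id: p for p in pairs}
    scored = [
        (by_id[v.pair_id], _passes(by_id[v.pair_id], v, criterion))
        for v in verdicts
    ]
    scored = [(p, ok) for p, ok in scored if ok is not None]
    replicated = [p for p, ok in scored if ok]
    contradicted = [p for p, ok in scored if not ok]
    empty_group = not replicated or not contradicted

    out: list[PredictorComparison] = []
    for name, flag in _CATEGORICAL.items():
        cats = {True: "RCT", False: "other"} if name == "original_design" else {
            True: "pharmacological",
            False: "nonpharmacological",
        }
        table = [
            [sum(flag(p) for p in replicated), sum(not flag(p) for p in replicated)],
            [sum(flag(p) for p in contradicted), sum(not flag(p) for p in contradicted)],
        ]
        summary = {
            "replicated": {cats[True]: table[0][0], cats[False]: table[0][1]},
            "contradicted": {cats[True]: table[1][0], cats[False]: table[1][1]},
        }
        p_val = None if empty_group else fisher_exact_2x2(table)
        out.append(
            PredictorComparison(
                predictor=name,
                criterion=criterion,
                test="fisher_exact",
                group_summary=summary,
                p=p_val,
            )
        )

    for name, getter in _CONTINUOUS.items():
        rep_vals = np.array([getter(p) for p in replicated if getter(p) is not None], float)
        con_vals = np.array([getter(p) for p in contradicted if getter(p) is not None], float)
        n_skipped = len(replicated) + len(contradicted) - rep_vals.size - con_vals.size
        if n_skipped:
            logger.info(
                "predictor %s / criterion %s: skipped %d pairs with missing values",
                name,
                criterion.value,
                n_skipped,
            )
        summary = {
            "replicated": _median_iqr(rep_vals) if rep_vals.size else {"n": 0},
            "contradicted": _median_iqr(con_vals) if con_vals.size else {"n": 0},
        }
        p_val = (
            mann_whitney_u(rep_vals, con_vals)
            if rep_vals.size and con_vals.size
            else None
        )
        out.append(
            PredictorComparison(
                predictor=name,
                criterion=criterion,
                test="mann_whitney",
                group_summary=summary,
                p=p_val,
            )
        )
    return out
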