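"""Random-effects pooling, leave-one-out re-estimation and replication eligibility.

Meta-analyses selected as replications usually include the highly cited
(index) study, so their pooled effect is not independent of it. This module
re-pools the remaining studies after removing the index: per-study effects
come from 2x2 arm counts when available (Mantel-Haenszel common-effect
estimate) or from published log effects with CI-derived standard errors, and
the random-effects combination uses inverse-variance weights with the
DerSimonian-Laird moment estimator of between-study variance (tau^2,
truncated at zero).

Eligibility helpers implement the published selection rules: a meta-analysis
qualifies as a replication only if the index study contributes less than
half its sample size; the ratio of evidence published before versus after
the index study drives the publication-order inversion flag; and among
eligible candidates the largest sample wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import EffectEstimate, EffectMeasure, ParseError
from .interval_stats import ratio_from_2x2, se_from_ci

__all__ = [
    "MetaStudyRecord",
    "MetaAnalysisSet",
    "PooledResult",
    "EvidenceTier",
    "StudyDescriptor",
    "CandidateDescriptor",
    "check_meta_eligibility",
    "mh_common_log_effect",
    "pool_random_effects",
    "leave_one_out",
    "contribution_fraction",
    "preceding_mass_exceeds",
    "select_replication",
    "read_studies_csv",
]


@dataclass(frozen=True)
class MetaStudyRecord:
    """One study row of a meta-analysis.

    Either ``arm_counts`` (events_a, total_a, events_b, total_b) or the pair
    (``log_effect``, ``se``) must be present; ``is_index`` marks the highly
    cited study.
    """

    study_id: str
    publication_year: Optional[int] = None
    n: Optional[int] = None
    arm_counts: Optional[tuple[int, int, int, int]] = None
    log_effect: Optional[float] = None
    se: Optional[float] = None
    is_index: bool = False

    def __post_init__(self) -> None:
        has_counts = self.arm_counts is not None
        has_effect = self.log_effect is not None and self.se is not None
        if not (has_counts or has_effect):
            raise ValueError(
                f"study {self.study_id!r}: needs arm_counts or (log_effect, se)"
            )
        if self.se is not None and self.se <= 0:
            raise ValueError(f"study {self.study_id!r}: se must be > 0")


@dataclass(frozen=True)
class MetaAnalysisSet:
    """The studies of one meta-analysis plus the effect measure pooled."""

    studies: tuple[MetaStudyRecord, ...]
    measure: EffectMeasure = EffectMeasure.RR

    def __post_init__(self) -> None:
        if len(self.studies) == 0:
            raise ValueError("a meta-analysis needs at least one study")
        n_index = sum(s.is_index for s in self.studies)
        if n_index > 1:
            raise ValueError(f"at most one index study allowed, found {n_index}")

    @property
    def index_study(self) -> Optional[MetaStudyRecord]:
        for s in self.studies:
            if s.is_index:
                return s
        return None


@dataclass(frozen=True)
class PooledResult:
    """Random-effects pooled estimate with heterogeneity diagnostics."""

    estimate: EffectEstimate
    k: int
    tau2: float
    q: float
    method: str  # "MH+DL", "IV+DL" or "single-study"

    @property
    def single_study(self) -> bool:
        return self.k == 1


def _study_effect(study: MetaStudyRecord, measure: EffectMeasure) -> tuple[float, float]:
    """(log effect, se) for one study, from counts when available."""
    if study.arm_counts is not None:
        est = ratio_from_2x2(*study.arm_counts, target=measure)
        return math.log(est.point), se_from_ci(est)
    return float(study.log_effect), float(study.se)


def _dl_tau2(y: np.ndarray, se: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird moment estimator: (tau^2 truncated at 0, Q)."""
    w = 1.0 / se**2
    mu_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    k = len(y)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return tau2, q


def mh_common_log_effect(sets: Sequence[tuple[int, int, int, int]], measure: EffectMeasure) -> float:
    """Mantel-Haenszel common-effect estimate on the log scale.

    RR weights are c*n1/(n1+n2) applied to per-stratum risk ratios; OR uses
    the classic ad/n over bc/n sums.
    """
    if measure is EffectMeasure.OR:
        num = sum(a * (t2 - c) / (t1 + t2) for a, t1, c, t2 in sets)
        den = sum((t1 - a) * c / (t1 + t2) for a, t1, c, t2 in sets)
    else:
        num = sum(a * t2 / (t1 + t2) for a, t1, c, t2 in sets)
        den = sum(c * t1 / (t1 + t2) for a, t1, c, t2 in sets)
    if num <= 0 or den <= 0:
        raise ValueError("Mantel-Haenszel estimate undefined (zero margin)")
    return math.log(num / den)


def pool_random_effects(analysis: MetaAnalysisSet) -> PooledResult:
    """Pool a meta-analysis with a DerSimonian-Laird random-effects model.

    When every study carries arm counts, the common-effect stage uses
    Mantel-Haenszel weighting (reported in the method tag) and per-study
    effects for the heterogeneity step come from the 2x2 tables; otherwise
    pooling is pure inverse-variance on (log_effect, se). The random-effects
    combination always applies inverse-variance weights 1/(se^2 + tau^2).
    A single-study set is returned unchanged, flagged ``single-study``.
    """
    studies = analysis.studies
    measure = analysis.measure
    effects = [_study_effect(s, measure) for s in studies]
    y = np.array([e[0] for e in effects])
    se = np.array([e[1] for e in effects])

    if len(studies) == 1:
        est = _estimate_from_log(y[0], se[0], measure)
        return PooledResult(estimate=est, k=1, tau2=0.0, q=0.0, method="single-study")

    tau2, q = _dl_tau2(y, se)
    w_re = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    se_mu = float(1.0 / math.sqrt(np.sum(w_re)))

    all_counts = all(s.arm_counts is not None for s in studies)
    method = "IV+DL"
    if all_counts and measure in (EffectMeasure.OR, EffectMeasure.RR):
        method = "MH+DL"
        if tau2 == 0.0:
            # With no between-study variance the random-effects estimate
            # collapses onto the Mantel-Haenszel common effect.
            mu = mh_common_log_effect([s.arm_counts for s in studies], measure)

    est = _estimate_from_log(mu, se_mu, measure)
    return PooledResult(estimate=est, k=len(studies), tau2=tau2, q=q, method=method)


def _estimate_from_log(log_point: float, se: float, measure: EffectMeasure) -> EffectEstimate:
    z = stats.norm.ppf(0.975)
    return EffectEstimate(
        measure=measure,
        point=math.exp(log_point),
        lo=math.exp(log_point - z * se),
        hi=math.exp(log_point + z * se),
        level=0.95,
    )


def leave_one_out(analysis: MetaAnalysisSet) -> PooledResult:
    """Re-pool after removing the index (highly cited) study.

    With exactly one remaining study, that study's effect is returned
    verbatim — the two-study rule: a 2-study meta-analysis reduces to the
    other study as the replication.
    """
    if analysis.index_study is None:
        raise ValueError("no index study to remove")
    rest = tuple(s for s in analysis.studies if not s.is_index)
    if not rest:
        raise ValueError("only the index study present; nothing to pool")
    return pool_random_effects(MetaAnalysisSet(studies=rest, measure=analysis.measure))


def contribution_fraction(analysis: MetaAnalysisSet) -> float:
    """Fraction of the meta-analysis sample size contributed by the index study."""
    if analysis.index_study is None:
        raise ValueError("no index study")
    if any(s.n is None for s in analysis.studies):
        raise ValueError("all sample sizes must be known")
    total = sum(s.n for s in analysis.studies)
    return analysis.index_study.n / total


def check_meta_eligibility(analysis: MetaAnalysisSet) -> bool:
    """A meta-analysis is an eligible replication iff the index study
    accounts for less than half of its sample size."""
    return contribution_fraction(analysis) < 0.5


def preceding_mass_exceeds(analysis: MetaAnalysisSet) -> bool:
    """True iff the pooled sample size published strictly before the index
    study's year exceeds that published strictly after it.

    Drives the order-inversion flag for new datasets; ties resolve to False
    (strict inequality, year granularity).
    """
    index = analysis.index_study
    if index is None:
        raise ValueError("no index study")
    if any(s.publication_year is None or s.n is None for s in analysis.studies):
        raise ValueError("all publication years and sample sizes must be known")
    before = sum(s.n for s in analysis.studies if s.publication_year < index.publication_year)
    after = sum(s.n for s in analysis.studies if s.publication_year > index.publication_year)
    return before > after


class EvidenceTier:
    """Ordered strength-of-evidence tiers for replication eligibility."""

    UNCONTROLLED = 0
    COHORT = 1
    RCT = 2
    META_ANALYSIS = 3


@dataclass(frozen=True)
class StudyDescriptor:
    tier: int
    n: int


@dataclass(frozen=True)
class CandidateDescriptor:
    study_id: str
    tier: int
    n: int
    contribution: Optional[float] = None  # index fraction, meta-analyses only


def select_replication(
    original: StudyDescriptor, candidates: Sequence[CandidateDescriptor]
) -> Optional[CandidateDescriptor]:
    """Pick the replication among candidate studies, or None if unchallenged.

    Eligible candidates have a strictly higher evidence tier than the
    original, or the same tier with sample size >= the original's;
    meta-analyses must additionally have the index contribution < 0.5.
    The largest-n survivor wins, ties broken lexicographically by study_id.
    """
    eligible = []
    for c in candidates:
        if c.tier == EvidenceTier.META_ANALYSIS and c.contribution is not None:
            if not (c.contribution < 0.5):
                continue
        if c.tier > original.tier or (c.tier == original.tier and c.n >= original.n):
            eligible.append(c)
    if not eligible:
        return None
    return min(eligible, key=lambda c: (-c.n, c.study_id))


STUDIES_CSV_COLUMNS = [
    "study_id",
    "year",
    "n",
    "events_a",
    "total_a",
    "events_b",
    "total_b",
    "log_effect",
    "se",
    "is_index",
]


def read_studies_csv(path: str | Path, measure: EffectMeasure = EffectMeasure.RR) -> MetaAnalysisSet:
    """Read a meta-analysis study table (same CSV dialect as the pair table)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("study_id", "is_index") if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    def opt(row, col):
        raw = str(row.get(col, "")).strip()
        return None if raw == "" else float(raw)

    records = []
    for _, row in frame.iterrows():
        label = str(row["study_id"]).strip()
        count_vals = [opt(row, c) for c in ("events_a", "total_a", "events_b", "total_b")]
        counts = None
        if all(v is not None for v in count_vals):
            counts = tuple(int(v) for v in count_vals)
        year = opt(row, "year")
        n = opt(row, "n")
        records.append(
            MetaStudyRecord(
                study_id=label,
                publication_year=None if year is None else int(year),
                n=None if n is None else int(n),
                arm_counts=counts,
                log_effect=opt(row, "log_effect"),
                se=opt(row, "se"),
                is_index=str(row["is_index"]).strip().lower() in {"true", "1", "yes"},
            )
        )
    return MetaAnalysisSet(studies=tuple(records), measure=measure)
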