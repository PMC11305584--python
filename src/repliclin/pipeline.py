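"""End-to-end analysis driver: verdicts, rates, inflation rows, predictors, report.

:func:`run_full_analysis` composes the criteria, inflation and predictor
modules over a pair table and returns an :class:`AnalysisReport` that
serializes to JSON and reconstructs losslessly. Rounding for display (whole
percents for rates, two decimals for inflation ratios) happens only at the
report layer; all stored values keep full precision.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

from . import __version__ as _pkg_version
from .core_data import Design, Direction, EffectMeasure, PairTable
from .inflation import (
    InflationRecord,
    InflationSummary,
    MissingDataError,
    coin_pair,
    pair_ratio,
    summarize_inflation,
)
from .predictors import PredictorComparison, compare_predictors
from .replication_criteria import (
    Criterion,
    CriterionRate,
    ReplicationVerdict,
    TriState,
    assess_pair,
    criterion_rates,
)

__all__ = ["AnalysisReport", "run_full_analysis", "report_from_dict", "INFLATION_ANALYSES"]

logger = logging.getLogger(__name__)

#: The four inflation sensitivity analyses: (name, apply order inversion, coin).
INFLATION_ANALYSES = [
    ("main", True, False),
    ("publication_order", False, False),
    ("coining", True, True),
    ("publication_order_coining", False, True),
]

_PREDICTOR_CRITERIA = [Criterion.SIGNIFICANCE, Criterion.OVERLAP, Criterion.AGGREGATE]


@dataclass(frozen=True)
class AnalysisReport:
    """Full analysis output: rates, inflation analyses, verdicts, predictors."""

    rates: tuple[CriterionRate, ...]
    inflation: dict  # analysis name -> subgroup name -> InflationSummary
    inflation_records: dict  # analysis name -> tuple[InflationRecord, ...]
    verdicts: tuple[ReplicationVerdict, ...]
    predictors: dict  # criterion value -> tuple[PredictorComparison, ...]
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "provenance": dict(self.provenance),
            "criterion_rates": {r.criterion.value: _rate_to_dict(r) for r in self.rates},
            "inflation": {
                name: {sub: _summary_to_dict(s) for sub, s in groups.items()}
                for name, groups in self.inflation.items()
            },
            "inflation_records": {
                name: [dataclasses.asdict(r) for r in recs]
                for name, recs in self.inflation_records.items()
            },
            "verdicts": [_verdict_to_dict(v) for v in self.verdicts],
            "predictors": {
                crit: [_comparison_to_dict(c) for c in comps]
                for crit, comps in self.predictors.items()
            },
        }


def _rate_to_dict(r: CriterionRate) -> dict:
    return {
        "numerator": r.numerator,
        "denominator": r.denominator,
        "rate": "undefined (n=0)" if r.undefined else r.rate,
        "percent": None if r.undefined else round(100.0 * r.rate),
        "ci": None if r.ci is None else [r.ci[0], r.ci[1]],
        "ci_percent": None if r.ci is None else [round(100.0 * r.ci[0]), round(100.0 * r.ci[1])],
        "interval_method": r.interval_method,
    }


def _summary_to_dict(s: InflationSummary) -> dict:
    return {
        "mean_ratio": s.mean_ratio,
        "mean_ratio_2dp": round(s.mean_ratio, 2),
        "ci": None if s.ci is None else [s.ci[0], s.ci[1]],
        "p": s.p,
        "n": s.n,
        "subgroup": s.subgroup,
    }


def _verdict_to_dict(v: ReplicationVerdict) -> dict:
    return {
        "pair_id": v.pair_id,
        "sig_concordant": v.sig_concordant.value,
        "ci_overlap": v.ci_overlap,
        "forward_containment": v.forward_containment,
        "reverse_containment": v.reverse_containment,
        "aggregate": v.aggregate,
    }


def _comparison_to_dict(c: PredictorComparison) -> dict:
    return {
        "predictor": c.predictor,
        "criterion": c.criterion.value,
        "test": c.test,
        "group_summary": c.group_summary,
        "p": c.p,
    }


def report_from_dict(payload: dict) -> AnalysisReport:
    """Reconstruct an :class:`AnalysisReport` from its JSON payload."""
    rates = tuple(
        CriterionRate(
            criterion=Criterion(name),
            numerator=d["numerator"],
            denominator=d["denominator"],
            rate=None if d["denominator"] == 0 else d["rate"],
            ci=None if d["ci"] is None else (d["ci"][0], d["ci"][1]),
            interval_method=d["interval_method"],
        )
        for name, d in payload["criterion_rates"].items()
    )
    inflation = {
        name: {
            sub: InflationSummary(
                mean_ratio=d["mean_ratio"],
                ci=None if d["ci"] is None else (d["ci"][0], d["ci"][1]),
                p=d["p"],
                n=d["n"],
                subgroup=d["subgroup"],
            )
            for sub, d in groups.items()
        }
        for name, groups in payload["inflation"].items()
    }
    records = {
        name: tuple(InflationRecord(**r) for r in recs)
        for name, recs in payload["inflation_records"].items()
    }
    verdicts = tuple(
        ReplicationVerdict(
            pair_id=d["pair_id"],
            sig_concordant=TriState(d["sig_concordant"]),
            ci_overlap=d["ci_overlap"],
            forward_containment=d["forward_containment"],
            reverse_containment=d["reverse_containment"],
            aggregate=d["aggregate"],
        )
        for d in payload["verdicts"]
    )
    predictors = {
        crit: tuple(
            PredictorComparison(
                predictor=d["predictor"],
                criterion=Criterion(d["criterion"]),
                test=d["test"],
                group_summary=d["group_summary"],
                p=d["p"],
            )
            for d in comps
        )
        for crit, comps in payload["predictors"].items()
    }
    return AnalysisReport(
        rates=rates,
        inflation=inflation,
        inflation_records=records,
        verdicts=verdicts,
        predictors=predictors,
        provenance=dict(payload["provenance"]),
    )


def _inflation_analysis(
    pairs: PairTable, apply_inversion: bool, coin: bool
) -> tuple[dict, tuple[InflationRecord, ...], list[str]]:
    """One of the four inflation analyses over all/phase1/RCT subgroups."""
    records: list[InflationRecord] = []
    designs: dict[str, Design] = {}
    excluded: list[str] = []
    for pair in pairs:
        work = pair
        if coin:
            try:
                work = coin_pair(pair)
            except MissingDataError:
                logger.warning(
                    "pair %s: favorable RR without per-arm counts; excluded from coined analysis",
                    pair.pair_id,
                )
                excluded.append(pair.pair_id)
                continue
        records.append(pair_ratio(work, apply_inversion=apply_inversion, coined=coin))
        designs[pair.pair_id] = pair.original_design

    groups: dict[str, InflationSummary] = {}
    if records:
        groups["all"] = summarize_inflation(records, subgroup="all")
    for name, design in (("phase1", Design.PHASE1), ("RCT", Design.RCT)):
        sub = [r for r in records if designs[r.pair_id] is design]
        if sub:
            groups[name] = summarize_inflation(sub, subgroup=name)
    return groups, tuple(records), excluded


def run_full_analysis(
    pairs: PairTable,
    alpha: float = 0.05,
    interval: str = "wilson",
    input_label: str = "user",
) -> AnalysisReport:
    """Run criteria, rates, the four inflation analyses and predictor tests.

    Deterministic given the inputs and options. An empty table yields a
    report whose rates are flagged undefined rather than an exception.
    """
    verdicts = tuple(assess_pair(p, alpha=alpha) for p in pairs)
    rates = tuple(criterion_rates(verdicts, pairs, alpha=alpha, interval=interval))

    inflation: dict = {}
    inflation_records: dict = {}
    excluded: list[str] = []
    if len(pairs) > 0:
        for name, invert, coin in INFLATION_ANALYSES:
            groups, records, skipped = _inflation_analysis(pairs, invert, coin)
            inflation[name] = groups
            inflation_records[name] = records
            if coin and skipped:
                excluded = skipped

    predictors = {
        crit.value: tuple(compare_predictors(pairs, verdicts, crit))
        for crit in _PREDICTOR_CRITERIA
    }

    provenance = {
        "input": input_label,
        "package": "repliclin",
        "version": _pkg_version,
        "alpha": alpha,
        "rate_interval": interval,
        "boundary_rule": "closed (shared endpoints overlap/contain)",
        "coining_excluded_pairs": excluded,
    }
    return AnalysisReport(
        rates=rates,
        inflation=inflation,
        inflation_records=inflation_records,
        verdicts=verdicts,
        predictors=predictors,
        provenance=provenance,
    )


def summary_text(report: AnalysisReport) -> str:
    """Human-readable summary with display rounding (whole % / 2-dp ratios)."""
    lines = ["Replication criterion rates:"]
    for r in report.rates:
        if r.undefined:
            lines.append(f"  {r.criterion.value:28s} undefined (n=0)")
        else:
            lo, hi = r.ci
            lines.append(
                f"  {r.criterion.value:28s} {r.numerator}/{r.denominator} = "
                f"{round(100 * r.rate)}% [{round(100 * lo)}, {round(100 * hi)}] "
                f"({r.interval_method})"
            )
    lines.append("Effect-size inflation (geometric mean ratio):")
    for name, groups in report.inflation.items():
        parts = []
        for sub in ("all", "phase1", "RCT"):
            if sub in groups:
                s = groups[sub]
                parts.append(f"{sub}={s.mean_ratio:.2f} (n={s.n})")
        p_all = groups.get("all")
        p_txt = f", p={p_all.p:.2f}" if p_all is not None and p_all.p is not None else ""
        lines.append(f"  {name:28s} " + "  ".join(parts) + p_txt)
    return "\n".join(lines)
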