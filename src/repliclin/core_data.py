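"""Domain types for study pairs, the pair-table CSV schema, and the packaged fixture.

The central object is the :class:`StudyPair`: one highly cited clinical study
and the replication selected for it, each summarized by an effect measure
(OR, RR, HR, IRR or ORR) with a point estimate and 95% confidence interval,
plus the annotations the downstream analyses need (outcome direction,
original-significance status, publication-order inversion, study design and
intervention type).

A transcription of the 24 published pairs analysed in the source study is
packaged as a CSV fixture and exposed through :func:`load_fixture_table3`.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "EffectMeasure",
    "Direction",
    "Significance",
    "Design",
    "InterventionType",
    "EffectEstimate",
    "StudyPair",
    "PairTable",
    "ParseError",
    "ValidationError",
    "read_pairs_csv",
    "write_pairs_csv",
    "load_fixture_table3",
    "write_report_json",
    "PAIR_TABLE_COLUMNS",
]


class ParseError(ValueError):
    """A CSV cell could not be parsed; message names row and column."""


class ValidationError(ValueError):
    """A domain invariant was violated; message names the offending pair."""


class EffectMeasure(enum.Enum):
    """Outcome effect measure.

    ORR (objective response rate) is a proportion in [0, 1]; the remaining
    kinds are strictly positive ratio measures analysed on the natural-log
    scale.
    """

    OR = "OR"
    RR = "RR"
    HR = "HR"
    IRR = "IRR"
    ORR = "ORR"

    @property
    def is_ratio(self) -> bool:
        return self is not EffectMeasure.ORR


class Direction(enum.Enum):
    """Whether effectiveness increases (favorable) or decreases (unfavorable)
    with the outcome measure.

    Death or tumour progression are unfavorable outcomes; neurologic
    improvement or tumour response are favorable ones.
    """

    FAVORABLE = "favorable"
    UNFAVORABLE = "unfavorable"


class Significance(enum.Enum):
    """Statistical-significance status of the original study's primary outcome.

    ``NOT_APPLICABLE`` is used for uncontrolled designs (phase 1 trials) that
    report no hypothesis test.
    """

    SIGNIFICANT = "significant"
    NONSIGNIFICANT = "nonsignificant"
    NOT_APPLICABLE = "not_applicable"


class Design(enum.Enum):
    RCT = "RCT"
    PHASE1 = "phase1"
    COHORT = "cohort"


class InterventionType(enum.Enum):
    PHARMACOLOGICAL = "pharmacological"
    NONPHARMACOLOGICAL = "nonpharmacological"


@dataclass(frozen=True)
class EffectEstimate:
    """A single study's effect: measure kind, point estimate and CI bounds.

    Invariants: ``lo <= point <= hi``; ratio measures require ``lo > 0``;
    ORR requires ``0 <= lo`` and ``hi <= 1``.
    """

    measure: EffectMeasure
    point: float
    lo: float
    hi: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValidationError(f"confidence level must be in (0,1), got {self.level}")
        if not (self.lo <= self.point <= self.hi):
            raise ValidationError(
                f"interval must contain the point estimate: "
                f"{self.lo} <= {self.point} <= {self.hi} fails"
            )
        if self.measure.is_ratio:
            if self.lo <= 0:
                raise ValidationError(
                    f"ratio measure {self.measure.value} requires lo > 0, got {self.lo}"
                )
        else:
            if self.lo < 0 or self.hi > 1:
                raise ValidationError(
                    f"ORR bounds must lie in [0,1], got [{self.lo}, {self.hi}]"
                )

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lo, self.hi)


@dataclass(frozen=True)
class StudyPair:
    """An original/replication estimate pair with its analysis annotations."""

    pair_id: str
    original: EffectEstimate
    replication: EffectEstimate
    direction: Direction
    original_significant: Significance
    order_inverted: bool
    original_design: Design
    intervention_type: InterventionType
    citations_per_year: Optional[float] = None
    original_n: Optional[int] = None
    original_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.original.measure is not self.replication.measure:
            raise ValidationError(
                f"pair {self.pair_id!r}: measures differ "
                f"({self.original.measure.value} vs {self.replication.measure.value}); "
                "convert estimates upstream before pairing"
            )
        if (
            self.original_design is Design.PHASE1
            and self.original_significant is not Significance.NOT_APPLICABLE
        ):
            raise ValidationError(
                f"pair {self.pair_id!r}: phase-1 originals carry no significance flag"
            )
        if self.citations_per_year is not None and self.citations_per_year < 0:
            raise ValidationError(f"pair {self.pair_id!r}: citations_per_year < 0")
        if self.original_n is not None and self.original_n <= 0:
            raise ValidationError(f"pair {self.pair_id!r}: original_n must be positive")
        if self.original_p is not None and not (0.0 <= self.original_p <= 1.0):
            raise ValidationError(f"pair {self.pair_id!r}: original_p outside [0,1]")

    @property
    def measure(self) -> EffectMeasure:
        return self.original.measure


@dataclass(frozen=True)
class PairTable:
    """Ordered collection of :class:`StudyPair` with unique identifiers."""

    rows: tuple[StudyPair, ...]

    def __post_init__(self) -> None:
        ids = [p.pair_id for p in self.rows]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate pair_id values: {sorted(dupes)}")

    def __iter__(self) -> Iterator[StudyPair]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, key: int | str) -> StudyPair:
        if isinstance(key, str):
            for p in self.rows:
                if p.pair_id == key:
                    return p
            raise KeyError(key)
        return self.rows[key]

    @classmethod
    def from_pairs(cls, pairs: Sequence[StudyPair]) -> "PairTable":
        return cls(rows=tuple(pairs))

    def filter(self, predicate) -> "PairTable":
        return PairTable(rows=tuple(p for p in self.rows if predicate(p)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([_pair_to_record(p) for p in self.rows], columns=PAIR_TABLE_COLUMNS)


#: Exact column names of the pair-table CSV schema, in order.
PAIR_TABLE_COLUMNS = [
    "pair_id",
    "measure",
    "orig_point",
    "orig_lo",
    "orig_hi",
    "rep_point",
    "rep_lo",
    "rep_hi",
    "direction",
    "original_significant",
    "order_inverted",
    "original_design",
    "intervention_type",
    "citations_per_year",
    "original_n",
    "original_p",
]

_OPTIONAL_COLUMNS = ("citations_per_year", "original_n", "original_p")


def _pair_to_record(p: StudyPair) -> dict:
    return {
        "pair_id": p.pair_id,
        "measure": p.measure.value,
        "orig_point": p.original.point,
        "orig_lo": p.original.lo,
        "orig_hi": p.original.hi,
        "rep_point": p.replication.point,
        "rep_lo": p.replication.lo,
        "rep_hi": p.replication.hi,
        "direction": p.direction.value,
        "original_significant": p.original_significant.value,
        "order_inverted": "true" if p.order_inverted else "false",
        "original_design": p.original_design.value,
        "intervention_type": p.intervention_type.value,
        "citations_per_year": "" if p.citations_per_year is None else p.citations_per_year,
        "original_n": "" if p.original_n is None else p.original_n,
        "original_p": "" if p.original_p is None else p.original_p,
    }


def _cell_float(raw: object, row_label: str, column: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"row {row_label!r}, column {column!r}: cannot parse {raw!r} as a number")
    if math.isnan(value):
        raise ParseError(f"row {row_label!r}, column {column!r}: missing value not allowed")
    return value


def _cell_optional_float(raw: object, row_label: str, column: str) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"row {row_label!r}, column {column!r}: cannot parse {raw!r} as a number")


def _cell_enum(enum_cls, raw: object, row_label: str, column: str):
    try:
        return enum_cls(str(raw).strip())
    except ValueError:
        allowed = [e.value for e in enum_cls]
        raise ParseError(
            f"row {row_label!r}, column {column!r}: {raw!r} is not one of {allowed}"
        )


def _cell_bool(raw: object, row_label: str, column: str) -> bool:
    text = str(raw).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ParseError(f"row {row_label!r}, column {column!r}: {raw!r} is not a boolean")


def read_pairs_csv(path: str | Path) -> PairTable:
    """Read a pair table from a UTF-8, comma-delimited CSV with a header row.

    Column names must match :data:`PAIR_TABLE_COLUMNS`; the three optional
    columns (``citations_per_year``, ``original_n``, ``original_p``) may be
    absent or empty, in which case the values are treated as missing.

    Raises
    ------
    ParseError
        For a malformed numeric/enumeration cell, naming row and column.
    ValidationError
        For a violated estimate or pair invariant, naming the pair_id.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in PAIR_TABLE_COLUMNS if c not in _OPTIONAL_COLUMNS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    pairs: list[StudyPair] = []
    for _, row in frame.iterrows():
        label = str(row.get("pair_id", "?")).strip() or "?"
        measure = _cell_enum(EffectMeasure, row["measure"], label, "measure")
        original = EffectEstimate(
            measure=measure,
            point=_cell_float(row["orig_point"], label, "orig_point"),
            lo=_cell_float(row["orig_lo"], label, "orig_lo"),
            hi=_cell_float(row["orig_hi"], label, "orig_hi"),
        )
        replication = EffectEstimate(
            measure=measure,
            point=_cell_float(row["rep_point"], label, "rep_point"),
            lo=_cell_float(row["rep_lo"], label, "rep_lo"),
            hi=_cell_float(row["rep_hi"], label, "rep_hi"),
        )
        n_raw = _cell_optional_float(row.get("original_n"), label, "original_n")
        pairs.append(
            StudyPair(
                pair_id=label,
                original=original,
                replication=replication,
                direction=_cell_enum(Direction, row["direction"], label, "direction"),
                original_significant=_cell_enum(
                    Significance, row["original_significant"], label, "original_significant"
                ),
                order_inverted=_cell_bool(row["order_inverted"], label, "order_inverted"),
                original_design=_cell_enum(
                    Design, row["original_design"], label, "original_design"
                ),
                intervention_type=_cell_enum(
                    InterventionType, row["intervention_type"], label, "intervention_type"
                ),
                citations_per_year=_cell_optional_float(
                    row.get("citations_per_year"), label, "citations_per_year"
                ),
                original_n=None if n_raw is None else int(n_raw),
                original_p=_cell_optional_float(row.get("original_p"), label, "original_p"),
            )
        )
    return PairTable.from_pairs(pairs)


def write_pairs_csv(table: PairTable, path: str | Path) -> None:
    """Write a pair table in the documented CSV schema (UTF-8, '.' decimals)."""
    table.to_dataframe().to_csv(path, index=False)


def load_fixture_table3() -> PairTable:
    """Load the packaged transcription of the 24 published study pairs.

    The table carries 7 uncontrolled phase-1 pairs measured by ORR and 17 RCT
    pairs measured by ratio effects; direction, significance, order-inversion
    and design flags are data transcribed from the source publication, not
    inferred from the numbers.
    """
    source = resources.files("repliclin.data").joinpath("table3_pairs.csv")
    with resources.as_file(source) as path:
        return read_pairs_csv(path)


def write_report_json(report, path: str | Path) -> None:
    """Serialize an analysis report (see :mod:`repliclin.pipeline`) to JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n", encoding="utf-8")
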