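"""Athlete records, cohort container and the delimited-file dialect.

A cohort is a flat table of athlete measurements: sex, age, serum IGF-I and
P-III-NP concentrations (µg/L, numerically identical to ng/mL) and the assay
used for each marker.  Three IGF-I assays (LC-MS/MS, Immunotech, IDS) and two
P-III-NP assays (Siemens, Orion) are in use, giving six assay pairs, each with
its own score scale.

The accepted file dialect is fixed: comma-separated, UTF-8, ``.`` decimal
separator, one header line with the canonical column names
``athlete_id, sex, age_years, igf1_ugL, p3np_ugL, igf1_assay, p3np_assay``.
Numeric fields are written with six decimal places so that
write → read → write is byte-identical.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gh2000")

__all__ = [
    "Sex",
    "Igf1Assay",
    "P3npAssay",
    "AssayPair",
    "ASSAY_PAIRS",
    "AthleteRecord",
    "CohortTable",
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "validate_record",
]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Igf1Assay(str, enum.Enum):
    """IGF-I assay platforms approved for the biomarker test."""

    LCMS = "LCMS"  # liquid chromatography-tandem mass spectrometry
    IMMUNOTECH = "IMMUNOTECH"
    IDS = "IDS"


class P3npAssay(str, enum.Enum):
    """P-III-NP assay platforms approved for the biomarker test."""

    SIEMENS = "SIEMENS"
    ORION = "ORION"


@dataclass(frozen=True, order=True)
class AssayPair:
    """One of the six (P-III-NP assay, IGF-I assay) combinations."""

    p3np_assay: P3npAssay
    igf1_assay: Igf1Assay

    @property
    def label(self) -> str:
        return f"{self.p3np_assay.value}-{self.igf1_assay.value}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: All six valid assay pairs, in the conventional report order
#: (Siemens rows first, LC-MS/MS - Immunotech - IDS within each).
ASSAY_PAIRS: tuple[AssayPair, ...] = tuple(
    AssayPair(p, i) for p in P3npAssay for i in Igf1Assay
)

COHORT_COLUMNS = (
    "athlete_id",
    "sex",
    "age_years",
    "igf1_ugL",
    "p3np_ugL",
    "igf1_assay",
    "p3np_assay",
)

_FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class AthleteRecord:
    """A single athlete measurement row.

    Marker concentrations may be missing (``None``); analyses drop rows
    missing the markers they need, which is why per-assay-pair sample sizes
    differ within one cohort.
    """

    athlete_id: str
    sex: Sex
    age_years: float
    igf1_ugL: float | None
    p3np_ugL: float | None
    igf1_assay: Igf1Assay
    p3np_assay: P3npAssay

    @property
    def assay_pair(self) -> AssayPair:
        return AssayPair(self.p3np_assay, self.igf1_assay)


def validate_record(record: AthleteRecord) -> list[str]:
    """Return a list of invariant violations; empty iff the record is valid."""
    problems: list[str] = []
    if not record.athlete_id:
        problems.append("athlete_id must be non-empty")
    if not isinstance(record.sex, Sex):
        problems.append(f"sex must be one of {[s.value for s in Sex]}")
    age = record.age_years
    if age is None or not np.isfinite(age):
        problems.append("age_years is missing or non-finite")
    elif age <= 0:
        problems.append("age_years must be positive")
    for name, value in (("igf1_ugL", record.igf1_ugL), ("p3np_ugL", record.p3np_ugL)):
        if value is None:
            continue  # missing markers are allowed
        if not np.isfinite(value):
            problems.append(f"{name} is non-finite")
        elif value <= 0:
            problems.append(f"{name} must be positive")
    if not isinstance(record.igf1_assay, Igf1Assay):
        problems.append(f"igf1_assay must be one of {[a.value for a in Igf1Assay]}")
    if not isinstance(record.p3np_assay, P3npAssay):
        problems.append(f"p3np_assay must be one of {[a.value for a in P3npAssay]}")
    return problems


@dataclass
class CohortTable:
    """Ordered, validated collection of :class:`AthleteRecord`.

    Iteration order is stable so downstream statistics are deterministic.
    ``provenance`` is a free-text label (source file or simulation
    parameters).
    """

    records: list[AthleteRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.athlete_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"athlete_id not unique within table: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AthleteRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.records == other.records

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame view with the canonical columns."""
        return pd.DataFrame(
            {
                "athlete_id": [r.athlete_id for r in self.records],
                "sex": [r.sex.value for r in self.records],
                "age_years": [r.age_years for r in self.records],
                "igf1_ugL": [np.nan if r.igf1_ugL is None else r.igf1_ugL for r in self.records],
                "p3np_ugL": [np.nan if r.p3np_ugL is None else r.p3np_ugL for r in self.records],
                "igf1_assay": [r.igf1_assay.value for r in self.records],
                "p3np_assay": [r.p3np_assay.value for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "") -> "CohortTable":
        records = [
            AthleteRecord(
                athlete_id=str(row.athlete_id),
                sex=Sex(row.sex),
                age_years=float(row.age_years),
                igf1_ugL=None if pd.isna(row.igf1_ugL) else float(row.igf1_ugL),
                p3np_ugL=None if pd.isna(row.p3np_ugL) else float(row.p3np_ugL),
                igf1_assay=Igf1Assay(row.igf1_assay),
                p3np_assay=P3npAssay(row.p3np_assay),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(records=records, provenance=provenance)

    def subset_pair(self, pair: AssayPair) -> "CohortTable":
        """Records of one assay pair with both of its markers present."""
        kept = [
            r
            for r in self.records
            if r.assay_pair == pair and r.igf1_ugL is not None and r.p3np_ugL is not None
        ]
        return CohortTable(records=kept, provenance=f"{self.provenance}[{pair.label}]")


def _parse_row(raw: Mapping[str, object], row_number: int, strict: bool) -> AthleteRecord | None:
    def num(col: str, required: bool) -> float | None:
        value = raw[col]
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            if required:
                raise ValueError(f"row {row_number}: missing value in column '{col}'")
            return None
        try:
            return float(value)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise ValueError(f"row {row_number}: unparseable numeric '{value}' in column '{col}'")

    try:
        record = AthleteRecord(
            athlete_id=str(raw["athlete_id"]),
            sex=Sex(str(raw["sex"]).strip().lower()),
            age_years=num("age_years", required=True),  # type: ignore[arg-type]
            igf1_ugL=num("igf1_ugL", required=False),
            p3np_ugL=num("p3np_ugL", required=False),
            igf1_assay=Igf1Assay(str(raw["igf1_assay"]).strip().upper()),
            p3np_assay=P3npAssay(str(raw["p3np_assay"]).strip().upper()),
        )
    except ValueError as exc:
        if strict:
            raise ValueError(f"row {row_number}: {exc}") from exc
        logger.warning("dropping row %d: %s", row_number, exc)
        return None
    problems = validate_record(record)
    if problems:
        if strict:
            raise ValueError(f"row {row_number}: " + "; ".join(problems))
        logger.warning("dropping row %d: %s", row_number, "; ".join(problems))
        return None
    return record


def read_cohort(path: str | Path, strict: bool = False) -> CohortTable:
    """Read a cohort CSV in the canonical dialect.

    In non-strict mode rows violating record invariants (non-positive age or
    marker, unknown assay, unparseable numeric) are dropped with a logged
    warning; in strict mode any such row raises :class:`ValueError` naming the
    row.  A missing mandatory column is always a hard error.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    records = []
    for i, raw in enumerate(frame[list(COHORT_COLUMNS)].to_dict("records"), start=2):
        rec = _parse_row(raw, i, strict)
        if rec is not None:
            records.append(rec)
    return CohortTable(records=records, provenance=str(path))


def write_cohort(
    table: CohortTable,
    path: str | Path,
    extra_columns: Mapping[str, Sequence[float]] | None = None,
) -> int:
    """Write a cohort CSV; returns the number of rows written.

    ``extra_columns`` (e.g. computed scores) are appended after the canonical
    columns in the given order; each must have one value per record.
    """
    n = len(table)
    extra_columns = dict(extra_columns or {})
    for name, values in extra_columns.items():
        if len(values) != n:
            raise ValueError(f"extra column '{name}' has length {len(values)}, expected {n}")
    frame = table.to_frame()
    for name, values in extra_columns.items():
        frame[name] = np.asarray(values, dtype=float)
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else _FLOAT_FMT % v)
    out.to_csv(path, index=False, lineterminator="\n")
    return n
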