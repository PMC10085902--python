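"""CSV readers and writers with row-level validation.

All files are UTF-8 CSV with a header row and "." as the decimal
separator.  Malformed rows are reported with their 1-based data row
number so bench records can be fixed quickly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diagnostics import MediumMeasurement, TissueMeasurement

__all__ = [
    "CsvFormatError",
    "CaseInput",
    "read_field_counts_csv",
    "write_field_counts_csv",
    "read_cases_csv",
    "write_cases_csv",
]

CASE_COLUMNS = ["case_id", "sample_kind", "size_g_or_ml", "diatom_count", "flags"]
SAMPLE_KINDS = {"lung", "liver", "kidney", "medium"}


class CsvFormatError(ValueError):
    """A CSV file violated the expected schema."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CsvFormatError(f"{path}: missing required columns {missing}")


def read_field_counts_csv(path) -> np.ndarray:
    """Read per-field counts (columns field_index, count) ordered by
    field index; returns the count vector."""
    df = pd.read_csv(path)
    _require_columns(df, ["field_index", "count"], path)
    counts = np.full(len(df), -1, dtype=np.int64)
    for row_no, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            idx = int(rec.field_index)
            cnt = int(rec.count)
        except (TypeError, ValueError) as exc:
            raise CsvFormatError(f"{path}: row {row_no}: non-integer value") from exc
        if cnt < 0:
            raise CsvFormatError(f"{path}: row {row_no}: negative count {cnt}")
        if not 0 <= idx < len(df) or counts[idx] != -1:
            raise CsvFormatError(
                f"{path}: row {row_no}: field_index {idx} out of range or duplicated"
            )
        counts[idx] = cnt
    return counts


def write_field_counts_csv(path, counts: Sequence[int]) -> None:
    pd.DataFrame(
        {"field_index": np.arange(len(counts)), "count": np.asarray(counts)}
    ).to_csv(path, index=False)


@dataclass
class CaseInput:
    """Measurements of one case parsed from a case CSV."""

    case_id: str
    lung: TissueMeasurement | None = None
    medium: MediumMeasurement | None = None
    peripheral_counts: dict | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.peripheral_counts is None:
            self.peripheral_counts = {}


def read_cases_csv(path) -> list[CaseInput]:
    """Read a long-format case table.

    Schema: case_id, sample_kind in {lung, liver, kidney, medium},
    size_g_or_ml (grams for tissues, millilitres for medium),
    diatom_count, flags (semicolon-separated, may be empty).
    """
    df = pd.read_csv(path, dtype={"case_id": str, "flags": str}, keep_default_na=False)
    _require_columns(df, CASE_COLUMNS, path)
    cases: dict[str, CaseInput] = {}
    for row_no, rec in enumerate(df.itertuples(index=False), start=1):
        kind = str(rec.sample_kind)
        if kind not in SAMPLE_KINDS:
            raise CsvFormatError(
                f"{path}: row {row_no}: unknown sample_kind {kind!r}"
            )
        try:
            size = float(rec.size_g_or_ml)
            count = float(rec.diatom_count)
        except (TypeError, ValueError) as exc:
            raise CsvFormatError(f"{path}: row {row_no}: non-numeric value") from exc
        if size <= 0:
            raise CsvFormatError(
                f"{path}: row {row_no}: non-positive size {size}"
            )
        if count < 0:
            raise CsvFormatError(f"{path}: row {row_no}: negative count {count}")
        case = cases.setdefault(str(rec.case_id), CaseInput(case_id=str(rec.case_id)))
        row_flags = tuple(f for f in str(rec.flags).split(";") if f)
        case.flags = tuple(dict.fromkeys(case.flags + row_flags))
        if kind == "lung":
            case.lung = TissueMeasurement(tissue="lung", mass_g=size, diatom_count=count)
        elif kind == "medium":
            case.medium = MediumMeasurement(volume_ml=size, diatom_count=count)
        else:
            case.peripheral_counts[kind] = int(count)
    return list(cases.values())


def write_cases_csv(path, rows: Sequence[dict]) -> None:
    """Write case rows (dicts with the case CSV columns)."""
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, index=False)
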