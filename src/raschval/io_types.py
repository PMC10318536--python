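"""Data model and I/O for long-format balance-assessment tables.

One row per patient-observation: identifiers, demographics, optional
clinical covariates (EDSS, ABC, fall count) and 14 ordinal item scores,
each in 0..4.  Records with any missing item score are excluded at read
time (and counted); records with missing covariates are retained, since
covariates are only consumed by the external-validity stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

N_ITEMS = 14
ITEM_MAX = 4
ITEM_COLUMNS = tuple(f"BBS{i:02d}" for i in range(1, N_ITEMS + 1))

#: default column-name mapping (identity on our canonical header)
DEFAULT_SCHEMA: dict[str, str] = {
    "patient_id": "patient_id",
    "center": "center",
    "obs_index": "obs_index",
    "gender": "gender",
    "age": "age",
    "course": "course",
    "duration": "duration",
    "edss": "edss",
    "abc": "abc",
    "falls": "falls",
    **{c: c for c in ITEM_COLUMNS},
}

VALID_COURSES = ("RR", "SP", "PP")
VALID_GENDERS = ("male", "female")


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class RecordValidationError(ValueError):
    """A retained record violates a field invariant."""


@dataclass(frozen=True)
class AssessmentRecord:
    """A single observation of one patient."""

    patient_id: str
    center: str
    obs_index: int
    gender: str | None
    age: float | None
    course: str | None
    duration: float | None
    edss: float | None
    abc: float | None
    falls: int | None
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise RecordValidationError(
                f"patient {self.patient_id}: expected {N_ITEMS} item scores, "
                f"got {len(self.items)}"
            )
        for j, x in enumerate(self.items):
            if not (0 <= int(x) <= ITEM_MAX):
                raise RecordValidationError(
                    f"patient {self.patient_id}, item {ITEM_COLUMNS[j]}: "
                    f"score {x} outside [0, {ITEM_MAX}]"
                )
        if self.obs_index < 1:
            raise RecordValidationError(
                f"patient {self.patient_id}: obs_index must be >= 1"
            )
        if self.edss is not None and not (
            0.0 <= self.edss <= 10.0 and float(self.edss * 2).is_integer()
        ):
            raise RecordValidationError(
                f"patient {self.patient_id}: EDSS {self.edss} not in [0,10] "
                "with 0.5 steps"
            )
        if self.abc is not None and not (0.0 <= self.abc <= 100.0):
            raise RecordValidationError(
                f"patient {self.patient_id}: ABC {self.abc} outside [0,100]"
            )
        if self.falls is not None and self.falls < 0:
            raise RecordValidationError(
                f"patient {self.patient_id}: negative fall count"
            )

    @property
    def total(self) -> int:
        return int(sum(self.items))


@dataclass
class ReadResult:
    records: list[AssessmentRecord]
    n_input: int
    n_excluded_missing_items: int


@dataclass
class ResponseMatrix:
    """Persons x items ordinal score matrix with per-row metadata."""

    values: np.ndarray  # (n, K) int
    item_max: np.ndarray  # (K,) int
    meta: pd.DataFrame  # one row per person-row of `values`

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        self.item_max = np.asarray(self.item_max, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != self.item_max.shape[0]:
            raise ValueError("item_max length does not match item count")
        if (self.values < 0).any() or (self.values > self.item_max).any():
            raise ValueError("item scores outside [0, item_max]")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("meta rows must match value rows")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def max_total(self) -> int:
        return int(self.item_max.sum())

    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    return float(v)


def _opt_int(v) -> int | None:
    f = _opt_float(v)
    return None if f is None else int(round(f))


def _opt_str(v) -> str | None:
    if v is None or pd.isna(v):
        return None
    return str(v)


def records_from_frame(
    df: pd.DataFrame, schema: Mapping[str, str] | None = None
) -> ReadResult:
    """Build validated records from a raw long-format frame.

    Rows with any missing item score are dropped (and counted); any
    retained row with an out-of-range item score raises.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    missing_cols = [src for src in schema.values() if src not in df.columns]
    if missing_cols:
        raise SchemaError(f"columns not found in input: {missing_cols}")

    item_src = [schema[c] for c in ITEM_COLUMNS]
    item_block = df[item_src]
    keep = item_block.notna().all(axis=1)
    n_excluded = int((~keep).sum())

    records: list[AssessmentRecord] = []
    for idx, row in df.loc[keep].iterrows():
        items = []
        for col, src in zip(ITEM_COLUMNS, item_src):
            raw = row[src]
            x = float(raw)
            if not x.is_integer() or not (0 <= x <= ITEM_MAX):
                raise RecordValidationError(
                    f"row {idx}, item {col}: score {raw} outside [0,{ITEM_MAX}]"
                )
            items.append(int(x))
        records.append(
            AssessmentRecord(
                patient_id=str(row[schema["patient_id"]]),
                center=str(row[schema["center"]]),
                obs_index=int(row[schema["obs_index"]]),
                gender=_opt_str(row[schema["gender"]]),
                age=_opt_float(row[schema["age"]]),
                course=_opt_str(row[schema["course"]]),
                duration=_opt_float(row[schema["duration"]]),
                edss=_opt_float(row[schema["edss"]]),
                abc=_opt_float(row[schema["abc"]]),
                falls=_opt_int(row[schema["falls"]]),
                items=tuple(items),
            )
        )
    return ReadResult(records, n_input=len(df), n_excluded_missing_items=n_excluded)


def read_assessments(
    path, schema: Mapping[str, str] | None = None, sep: str | None = None
) -> ReadResult:
    """Read a delimited assessment table (comma default, tab accepted)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return records_from_frame(df, schema)


def records_to_frame(records: Sequence[AssessmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        items = d.pop("items")
        d.update({c: items[j] for j, c in enumerate(ITEM_COLUMNS)})
        rows.append(d)
    return pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA))


def write_assessments(records: Sequence[AssessmentRecord], path, sep: str = ",") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def to_response_matrix(records: Sequence[AssessmentRecord]) -> ResponseMatrix:
    """One matrix row per record, columns BBS01..BBS14.

    Time-dependence across repeated observations is the sampling stage's
    concern, not handled here.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to convert")
    values = np.array([r.items for r in records], dtype=int)
    meta = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "center": [r.center for r in records],
            "obs_index": [r.obs_index for r in records],
            "gender": [r.gender for r in records],
            "age": [r.age for r in records],
            "course": [r.course for r in records],
            "duration": [r.duration for r in records],
            "edss": [r.edss for r in records],
            "abc": [r.abc for r in records],
            "falls": [r.falls for r in records],
            "total": [r.total for r in records],
        }
    )
    return ResponseMatrix(
        values=values, item_max=np.full(N_ITEMS, ITEM_MAX), meta=meta
    )
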