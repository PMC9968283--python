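"""Match-key projections and value transforms.

Linkage matches records on exact equality of canonicalized
``(timestamp-component, value-component)`` keys.  The projection mode
selects which part of the timestamp participates:

* ``datetime``   — the full date-time at second resolution (identity mode);
* ``date_only``  — the calendar date (year-month-day);
* ``time_only``  — the time of day at second resolution (86,400 levels);
* ``value_only`` — no timestamp component at all.

Value transforms coarsen the heart-rate value itself: truncation to an
integer (drop the fraction) and categorization into a lowercase letter
(``floor(value / 10)`` indexed into ``a..z``), which turns the series into
categorical data.  Transforms are applied to *both* tables symmetrically
before linkage; an asymmetric transform would make exact matching vacuous.
"""

from __future__ import annotations

import copy
import datetime as _dt
import enum
from typing import NamedTuple, Optional

import numpy as np

from .simulator import ErgoTable, PatTable, Reading

__all__ = [
    "ProjectionMode",
    "MatchKey",
    "project_key",
    "truncate_values",
    "categorize_values",
    "categorize_value",
    "canonical_values",
    "time_components",
    "timestamps_to_seconds",
]

SECONDS_PER_DAY = 86400
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


class ProjectionMode(str, enum.Enum):
    DATETIME = "datetime"
    DATE_ONLY = "date_only"
    TIME_ONLY = "time_only"
    VALUE_ONLY = "value_only"


class MatchKey(NamedTuple):
    """Canonical match key: integer time component (or None) + integer value.

    The time component is epoch seconds (``datetime``), days since epoch
    (``date_only``) or seconds since midnight (``time_only``).  The value
    component is the heart rate scaled to an integer: ``round(10 * value)``
    for raw one-decimal values, the value itself for integer-truncated
    tables, and the letter index 0..25 for categorical tables.
    """

    time_component: Optional[int]
    value_component: int


def timestamps_to_seconds(timestamps: np.ndarray) -> np.ndarray:
    """datetime64 array -> int64 epoch seconds."""
    return timestamps.astype("datetime64[s]").astype(np.int64)


def time_components(ts_seconds: np.ndarray, mode: ProjectionMode) -> np.ndarray | None:
    """Project int64 epoch seconds onto the mode's time component (vectorized)."""
    mode = ProjectionMode(mode)
    if mode is ProjectionMode.DATETIME:
        return ts_seconds
    if mode is ProjectionMode.DATE_ONLY:
        return np.floor_divide(ts_seconds, SECONDS_PER_DAY)
    if mode is ProjectionMode.TIME_ONLY:
        return np.mod(ts_seconds, SECONDS_PER_DAY)
    return None  # VALUE_ONLY


def canonical_values(values: np.ndarray, value_kind: str) -> np.ndarray:
    """Canonicalize a value column to comparable int64.

    Raw bpm values carry one fractional digit, so they scale exactly to
    integers as ``round(10 * v)``; exact float equality is never relied on.
    """
    if value_kind == "raw":
        return np.rint(np.asarray(values, dtype=np.float64) * 10.0).astype(np.int64)
    if value_kind in ("int", "letter"):
        return np.asarray(values, dtype=np.int64)
    raise ValueError(f"unknown value kind: {value_kind!r}")


def project_key(reading: Reading, mode: ProjectionMode, value_kind: str = "raw") -> MatchKey:
    """Project a single reading onto its canonical match key."""
    mode = ProjectionMode(mode)
    ts = np.asarray([np.datetime64(reading.timestamp, "s")])
    tsec = timestamps_to_seconds(ts)
    value = reading.value
    if value_kind == "letter" and isinstance(value, str):
        value = _LETTERS.index(value)
    vcomp = int(canonical_values(np.asarray([value]), value_kind)[0])
    tcomp = time_components(tsec, mode)
    return MatchKey(None if tcomp is None else int(tcomp[0]), vcomp)


# ---------------------------------------------------------------------------
# value transforms
# ---------------------------------------------------------------------------

def _transform_table(table, fn, out_kind):
    if table.value_kind == "letter":
        raise ValueError("table is already categorical (letter-valued)")
    out = copy.copy(table)
    out.records = []
    for rec in table.records:
        new = copy.copy(rec)
        new.values = fn(rec.values)
        new.timestamps = rec.timestamps  # untouched
        out.records.append(new)
    out.value_kind = out_kind
    return out


def truncate_values(table: ErgoTable | PatTable):
    """Drop the fractional part of every value (e.g. 94.3 -> 94).

    Timestamps are untouched.  Requires non-negative values, for which
    truncation equals the floor and never increases a value.
    """
    def trunc(values):
        v = np.asarray(values, dtype=np.float64)
        if np.any(v < 0):
            raise ValueError("truncate_values requires non-negative values")
        return np.trunc(v).astype(np.int64)
    return _transform_table(table, trunc, "int")


def categorize_values(table: ErgoTable | PatTable):
    """Map every value to a lowercase letter: index ``floor(value/10)`` of a..z.

    Values must lie in [0, 260) so the index lands in [0, 25].  The result
    behaves like categorical (e.g. blood-type-like) data under linkage.
    """
    def cat(values):
        v = np.asarray(values, dtype=np.float64)
        idx = np.floor(v / 10.0)
        if np.any((v < 0) | (idx > 25)):
            bad = v[(v < 0) | (idx > 25)][0]
            raise ValueError(f"value {bad} outside [0, 260) cannot be categorized")
        return idx.astype(np.int64)
    return _transform_table(table, cat, "letter")


def categorize_value(value: float) -> str:
    """Scalar letter coding: 94.3 -> 'j'."""
    if value < 0 or value >= 260:
        raise ValueError(f"value {value} outside [0, 260) cannot be categorized")
    return _LETTERS[int(value // 10)]
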