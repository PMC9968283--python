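"""Synthetic ergometric heart-rate data and the core table types.

An ergometric (exercise/stress) test produces a heart-rate time series with
three phases — warm-up, stress and recovery — sampled here at 1 Hz.  The
simulator draws, per test, a random *envelope*: the start timestamp, the
initial heart rate, a per-phase average slope and a noise standard
deviation.  The simulated series is the piecewise-linear envelope plus
i.i.d. Gaussian noise, rounded to one decimal digit of bpm.

Two tables are produced:

* :class:`ErgoTable` — the full database, one row per test, ``q`` readings
  per row (``p`` rows in total);
* :class:`PatTable` — the minimal released table, one row per released
  record with ``n`` sampled ``(timestamp, value)`` pairs (``m`` rows).

Ground truth (which patient performed which test) travels out-of-band in a
separate mapping / hidden field and is never written into released CSVs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Reading",
    "EnvelopeParams",
    "GeneratorConfig",
    "ErgoRecord",
    "ErgoTable",
    "PatRecord",
    "PatTable",
    "simulate_test",
    "simulate_cohort",
    "sample_pat",
    "write_truth_csv",
    "read_truth_csv",
]

#: supported representations of the heart-rate value column
VALUE_KINDS = ("raw", "int", "letter")

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


class InvalidConfigError(ValueError):
    """Raised for an invalid simulator configuration."""


class Reading(NamedTuple):
    """One (timestamp, value) pair — the atomic match unit.

    ``timestamp`` has second resolution (no sub-second component); ``value``
    is a heart rate in bpm with one fractional digit (or an integer /
    single lowercase letter after a value transform).
    """

    timestamp: np.datetime64
    value: object


@dataclasses.dataclass(frozen=True)
class EnvelopeParams:
    """Per-test random variables defining the shape of one simulated curve.

    Slopes are in bpm/second; ``noise_sd`` is the standard deviation of the
    additive Gaussian noise in bpm.
    """

    start_timestamp: np.datetime64
    initial_hr: float
    noise_sd: float
    slope_phase1: float
    slope_phase2: float
    slope_phase3: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


@dataclasses.dataclass
class GeneratorConfig:
    """Cohort-level configuration for :func:`simulate_cohort`.

    The envelope ranges are uniform-distribution bounds; each test draws its
    own envelope independently.  ``phase_length`` readings per phase at
    ``sampling_period_s`` seconds between readings (1 Hz by default).
    Within one patient, consecutive test windows are scheduled sequentially
    with a random gap drawn from ``gap_range_s`` so they never overlap;
    tests of *different* patients may overlap in time, which is what makes
    chance collisions possible under coarsened keys.
    """

    n_patients: int = 1600
    tests_per_patient: int = 20
    phase_length: int = 300
    sampling_period_s: int = 1
    start_window: tuple[str, str] = ("2024-01-01", "2026-01-01")
    initial_hr_range: tuple[float, float] = (60.0, 90.0)
    slope_phase1_range: tuple[float, float] = (0.05, 0.15)
    slope_phase2_range: tuple[float, float] = (0.10, 0.30)
    slope_phase3_range: tuple[float, float] = (-0.30, -0.10)
    noise_sd_range: tuple[float, float] = (0.5, 2.0)
    gap_range_s: tuple[int, int] = (3600, 7 * 86400)
    hr_floor: float = 30.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_patients < 1 or self.tests_per_patient < 1:
            raise InvalidConfigError("n_patients and tests_per_patient must be >= 1")
        if self.phase_length < 1:
            raise InvalidConfigError("phase_length must be >= 1")
        if self.sampling_period_s < 1:
            raise InvalidConfigError("sampling_period_s must be a positive whole number of seconds")
        if self.gap_range_s[0] < 1:
            raise InvalidConfigError("minimum inter-test gap must be >= 1 s")


def _as_seconds(ts) -> np.datetime64:
    return np.datetime64(ts, "s")


@dataclasses.dataclass
class ErgoRecord:
    """One ergometric test: an ordered series of readings.

    ``true_patient_id`` is a ground-truth side channel retained by the data
    holder; it is never written to a released file.
    """

    test_id: str
    true_patient_id: str | None
    timestamps: np.ndarray  # datetime64[s], strictly increasing
    values: np.ndarray      # float (raw) or int64 (int / letter index)

    @property
    def n_readings(self) -> int:
        return len(self.values)

    def readings(self, value_kind: str = "raw") -> list[Reading]:
        return [Reading(t, _display_value(v, value_kind))
                for t, v in zip(self.timestamps, self.values)]


@dataclasses.dataclass
class PatRecord:
    """One released record: a pseudonymous ID plus ``n`` sampled pairs."""

    released_id: str
    timestamps: np.ndarray  # datetime64[s], distinct
    values: np.ndarray
    true_test_id: str | None = None  # ground truth, test-only

    @property
    def n_pairs(self) -> int:
        return len(self.values)


def _display_value(v, kind: str):
    if kind == "letter":
        return _LETTERS[int(v)]
    if kind == "int":
        return int(v)
    return float(v)


@dataclasses.dataclass
class ErgoTable:
    """The full released time-series database: ``p`` tests × ``q`` readings."""

    records: list[ErgoRecord]
    value_kind: str = "raw"

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> ErgoRecord:
        return self.records[i]

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def patients(self) -> set[str]:
        return {r.true_patient_id for r in self.records if r.true_patient_id is not None}

    def validate(self) -> None:
        """Check per-record timestamp monotonicity and per-patient disjoint windows."""
        windows: dict[str, list[tuple[np.datetime64, np.datetime64]]] = {}
        for rec in self.records:
            if len(rec.timestamps) == 0:
                raise ValueError(f"test {rec.test_id} has no readings")
            if not np.all(np.diff(rec.timestamps.astype("datetime64[s]").astype(np.int64)) > 0):
                raise ValueError(f"test {rec.test_id} timestamps are not strictly increasing")
            if rec.true_patient_id is not None:
                windows.setdefault(rec.true_patient_id, []).append(
                    (rec.timestamps[0], rec.timestamps[-1]))
        for pid, ws in windows.items():
            ws.sort()
            for (s1, e1), (s2, _e2) in zip(ws, ws[1:]):
                if s2 <= e1:
                    raise ValueError(f"patient {pid} has overlapping test windows")

    # -- CSV interface: long format, one row per reading ------------------
    def to_csv(self, path) -> None:
        frames = []
        for rec in self.records:
            frames.append(pd.DataFrame({
                "test_id": rec.test_id,
                "reading_index": np.arange(rec.n_readings),
                "timestamp": pd.to_datetime(rec.timestamps).strftime("%Y-%m-%dT%H:%M:%S"),
                "value": _format_values(rec.values, self.value_kind),
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, value_kind: str = "raw") -> "ErgoTable":
        df = pd.read_csv(path, dtype={"test_id": str})
        records = []
        for test_id, g in df.groupby("test_id", sort=False):
            g = g.sort_values("reading_index")
            records.append(ErgoRecord(
                test_id=str(test_id),
                true_patient_id=None,
                timestamps=pd.to_datetime(g["timestamp"]).to_numpy().astype("datetime64[s]"),
                values=_parse_values(g["value"].to_numpy(), value_kind),
            ))
        return cls(records, value_kind=value_kind)


@dataclasses.dataclass
class PatTable:
    """The minimal identifying release: ``m`` records × ``n`` sampled pairs."""

    records: list[PatRecord]
    value_kind: str = "raw"

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> PatRecord:
        return self.records[i]

    @property
    def n_pairs(self) -> int:
        if not self.records:
            return 0
        return self.records[0].n_pairs

    def validate(self) -> None:
        n = self.n_pairs
        for i, rec in enumerate(self.records):
            if rec.n_pairs != n:
                raise ValueError(f"record {i} has {rec.n_pairs} pairs, expected {n}")
            if len(set(rec.timestamps.astype("datetime64[s]").astype(np.int64))) != rec.n_pairs:
                raise ValueError(f"record {i} has duplicate timestamps")

    def to_csv(self, path) -> None:
        # record_index disambiguates multiple released records that share a
        # pseudonymous patient ID (one patient, several tests).
        frames = []
        for i, rec in enumerate(self.records):
            frames.append(pd.DataFrame({
                "released_id": rec.released_id,
                "record_index": i,
                "pair_index": np.arange(rec.n_pairs),
                "timestamp": pd.to_datetime(rec.timestamps).strftime("%Y-%m-%dT%H:%M:%S"),
                "value": _format_values(rec.values, self.value_kind),
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, value_kind: str = "raw") -> "PatTable":
        df = pd.read_csv(path, dtype={"released_id": str})
        records = []
        for _, g in df.groupby("record_index", sort=True):
            g = g.sort_values("pair_index")
            records.append(PatRecord(
                released_id=str(g["released_id"].iloc[0]),
                timestamps=pd.to_datetime(g["timestamp"]).to_numpy().astype("datetime64[s]"),
                values=_parse_values(g["value"].to_numpy(), value_kind),
            ))
        return cls(records, value_kind=value_kind)


def _format_values(values: np.ndarray, kind: str):
    if kind == "letter":
        return [_LETTERS[int(v)] for v in values]
    if kind == "int":
        return values.astype(np.int64)
    return np.asarray([f"{float(v):.1f}" for v in values])


def _parse_values(col: np.ndarray, kind: str) -> np.ndarray:
    if kind == "letter":
        return np.asarray([_LETTERS.index(str(v)) for v in col], dtype=np.int64)
    if kind == "int":
        return np.asarray(col, dtype=np.int64)
    return np.asarray(col, dtype=np.float64)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def simulate_test(envelope: EnvelopeParams,
                  phase_length: int,
                  rng: np.random.Generator,
                  *,
                  sampling_period_s: int = 1,
                  hr_floor: float = 30.0,
                  test_id: str = "T0",
                  patient_id: str | None = None) -> ErgoRecord:
    """Simulate one three-phase test of ``3 * phase_length`` readings.

    Reading 0 equals ``initial_hr`` exactly (before noise); each subsequent
    reading advances by the active phase's slope.  Gaussian noise with sd
    ``noise_sd`` is added, values are rounded to one decimal and floored at
    ``hr_floor`` bpm so extreme noise draws cannot produce non-physiological
    values.
    """
    if phase_length < 1:
        raise InvalidConfigError("phase_length must be >= 1")
    if envelope.noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")

    q = 3 * phase_length
    slopes = np.empty(q)
    slopes[:phase_length] = envelope.slope_phase1
    slopes[phase_length:2 * phase_length] = envelope.slope_phase2
    slopes[2 * phase_length:] = envelope.slope_phase3
    # reading t = initial + sum of the slopes of steps 1..t (step 0 contributes 0)
    steps = np.concatenate(([0.0], slopes[1:] * sampling_period_s))
    env = envelope.initial_hr + np.cumsum(steps)
    noise = rng.normal(0.0, envelope.noise_sd, size=q) if envelope.noise_sd > 0 else 0.0
    values = np.round(env + noise, 1)
    values = np.maximum(values, hr_floor)

    start = _as_seconds(envelope.start_timestamp)
    timestamps = start + np.arange(q, dtype=np.int64) * np.timedelta64(sampling_period_s, "s")
    return ErgoRecord(test_id=test_id, true_patient_id=patient_id,
                      timestamps=timestamps, values=values)


def _draw_envelope(config: GeneratorConfig, start: np.datetime64,
                   rng: np.random.Generator) -> EnvelopeParams:
    u = rng.uniform
    return EnvelopeParams(
        start_timestamp=start,
        initial_hr=u(*config.initial_hr_range),
        noise_sd=u(*config.noise_sd_range),
        slope_phase1=u(*config.slope_phase1_range),
        slope_phase2=u(*config.slope_phase2_range),
        slope_phase3=u(*config.slope_phase3_range),
    )


def simulate_cohort(config: GeneratorConfig) -> tuple[ErgoTable, dict[str, str]]:
    """Simulate ``n_patients × tests_per_patient`` tests.

    Returns the table and a ground-truth mapping ``test_id -> patient_id``.
    Each patient's first test starts at a uniform random second inside
    ``start_window``; subsequent tests follow sequentially with a random gap,
    so one patient's windows are disjoint by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w0 = _as_seconds(config.start_window[0]).astype(np.int64)
    w1 = _as_seconds(config.start_window[1]).astype(np.int64)
    if w1 <= w0:
        raise InvalidConfigError("start_window must span a positive interval")

    q = 3 * config.phase_length
    duration = q * config.sampling_period_s
    records: list[ErgoRecord] = []
    truth: dict[str, str] = {}
    test_counter = 0
    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        start = int(rng.integers(w0, w1))
        for _t in range(config.tests_per_patient):
            tid = f"T{test_counter:06d}"
            test_counter += 1
            env = _draw_envelope(config, np.datetime64(start, "s"), rng)
            records.append(simulate_test(
                env, config.phase_length, rng,
                sampling_period_s=config.sampling_period_s,
                hr_floor=config.hr_floor, test_id=tid, patient_id=pid))
            truth[tid] = pid
            gap = int(rng.integers(config.gap_range_s[0], config.gap_range_s[1] + 1))
            start += duration + gap
    return ErgoTable(records), truth


def sample_pat(ergo: ErgoTable,
               indices: Sequence[int],
               released_ids: Mapping[str, str] | None = None) -> PatTable:
    """Project each test onto the readings at ``indices`` (verbatim pairs).

    One released record per test.  ``released_ids`` maps ``test_id`` to the
    pseudonymous identifier to attach; by default the (ground-truth) patient
    ID or, failing that, the test ID is used — suitable only for
    experiments, not for an actual release.
    """
    idx = np.asarray(list(indices), dtype=np.int64)
    if len(idx) == 0:
        raise ValueError("at least one sampling index is required")
    records = []
    for rec in ergo.records:
        bad = idx[(idx < 0) | (idx >= rec.n_readings)]
        if bad.size:
            raise IndexError(
                f"index {int(bad[0])} out of range for test {rec.test_id} "
                f"({rec.n_readings} readings)")
        if released_ids is not None:
            rid = released_ids[rec.test_id]
        else:
            rid = rec.true_patient_id if rec.true_patient_id is not None else rec.test_id
        records.append(PatRecord(
            released_id=rid,
            timestamps=rec.timestamps[idx].copy(),
            values=rec.values[idx].copy(),
            true_test_id=rec.test_id,
        ))
    return PatTable(records, value_kind=ergo.value_kind)


# ---------------------------------------------------------------------------
# truth file (test-only artifact; never part of a release)
# ---------------------------------------------------------------------------

def write_truth_csv(path, truth: Mapping[str, str],
                    released_ids: Mapping[str, str] | None = None,
                    record_index: Mapping[str, int] | None = None) -> None:
    rows = []
    for tid, pid in truth.items():
        rows.append({
            "test_id": tid,
            "patient_id": pid,
            "released_id": released_ids[tid] if released_ids else pid,
            "record_index": record_index[tid] if record_index else -1,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"test_id": str, "patient_id": str, "released_id": str})
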