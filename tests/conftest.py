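"""Shared fixtures and independent oracles.

The oracle here recomputes match counts by brute force — per released
record, per database row, plain membership tests on keys canonicalized by
its own scalar arithmetic — so it shares no code path with either linker.
"""

from __future__ import annotations

import numpy as np
import pytest

from serieslink import (
    ErgoRecord,
    ErgoTable,
    GeneratorConfig,
    PatRecord,
    PatTable,
    ProjectionMode,
    simulate_cohort,
)

BASE = np.datetime64("2024-06-01T00:00:00", "s")


def make_ergo(rows, value_kind="raw", base=BASE):
    """rows: list of list[(offset_seconds, value)] -> ErgoTable."""
    records = []
    for k, row in enumerate(rows):
        offs = np.asarray([o for o, _ in row], dtype=np.int64)
        vals = np.asarray([v for _, v in row],
                          dtype=np.float64 if value_kind == "raw" else np.int64)
        records.append(ErgoRecord(
            test_id=f"T{k}", true_patient_id=f"P{k}",
            timestamps=base + offs * np.timedelta64(1, "s"), values=vals))
    return ErgoTable(records, value_kind=value_kind)


def make_pat(rows, value_kind="raw", base=BASE, true_tests=None):
    records = []
    for i, row in enumerate(rows):
        offs = np.asarray([o for o, _ in row], dtype=np.int64)
        vals = np.asarray([v for _, v in row],
                          dtype=np.float64 if value_kind == "raw" else np.int64)
        records.append(PatRecord(
            released_id=f"R{i}",
            timestamps=base + offs * np.timedelta64(1, "s"), values=vals,
            true_test_id=None if true_tests is None else true_tests[i]))
    return PatTable(records, value_kind=value_kind)


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def _oracle_key(ts: np.datetime64, value, value_kind: str, mode: ProjectionMode):
    sec = int(np.datetime64(ts, "s").astype("int64"))
    if value_kind == "raw":
        v = round(float(value) * 10)
    else:
        v = int(value)
    mode = ProjectionMode(mode)
    if mode is ProjectionMode.DATETIME:
        return (sec, v)
    if mode is ProjectionMode.DATE_ONLY:
        return (sec // 86400, v)
    if mode is ProjectionMode.TIME_ONLY:
        return (sec % 86400, v)
    return (v,)


def oracle_counts(pat: PatTable, ergo: ErgoTable, mode) -> dict[tuple[int, int], int]:
    """Nested-loop membership counting: count(i, k) = #pairs of record i found in row k."""
    ergo_keysets = []
    for rec in ergo.records:
        ergo_keysets.append({_oracle_key(t, v, ergo.value_kind, mode)
                             for t, v in zip(rec.timestamps, rec.values)})
    out: dict[tuple[int, int], int] = {}
    for i, rec in enumerate(pat.records):
        keys = [_oracle_key(t, v, pat.value_kind, mode)
                for t, v in zip(rec.timestamps, rec.values)]
        for k, keyset in enumerate(ergo_keysets):
            c = sum(1 for key in keys if key in keyset)
            if c:
                out[(i, k)] = c
    return out


def oracle_report(pat, ergo, mode):
    """(max_count, argmax frozenset) per released record, from oracle_counts."""
    counts = oracle_counts(pat, ergo, mode)
    out = []
    for i in range(len(pat)):
        row = {k: c for (ii, k), c in counts.items() if ii == i}
        if not row:
            out.append((0, frozenset()))
        else:
            best = max(row.values())
            out.append((best, frozenset(k for k, c in row.items() if c == best)))
    return out


def random_instance(rng: np.random.Generator, max_m=12, max_p=12, max_q=12):
    """A small random linkage instance with engineered key collisions.

    Timestamps land inside a 3-day window on a coarse grid and values come
    from a handful of levels, so all projection modes see genuine ties.
    Roughly half the released records are verbatim samples of a database
    row; the rest are random pairs.
    """
    m = int(rng.integers(1, max_m + 1))
    p = int(rng.integers(1, max_p + 1))
    q = int(rng.integers(1, max_q + 1))
    n = int(rng.integers(1, min(4, q) + 1))
    values = np.round(np.linspace(60.0, 62.0, 6), 1)

    ergo_rows = []
    for _ in range(p):
        offs = rng.choice(3 * 86400 // 600, size=q, replace=False) * 600
        vals = rng.choice(values, size=q)
        ergo_rows.append(list(zip(offs.tolist(), vals.tolist())))
    pat_rows = []
    for _ in range(m):
        if rng.random() < 0.5:
            src = ergo_rows[int(rng.integers(p))]
            picks = rng.choice(len(src), size=n, replace=False)
            pat_rows.append([src[j] for j in picks])
        else:
            offs = rng.choice(3 * 86400 // 600, size=n, replace=False) * 600
            vals = rng.choice(values, size=n)
            pat_rows.append(list(zip(offs.tolist(), vals.tolist())))
    return make_pat(pat_rows), make_ergo(ergo_rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-patient cohort with short tests, shared across unit tests."""
    cfg = GeneratorConfig(n_patients=6, tests_per_patient=3, phase_length=40, seed=11)
    return simulate_cohort(cfg)
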