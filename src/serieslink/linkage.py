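"""Exact record linkage of released samples against a time-series database.

Two algorithms with identical output contracts:

* :func:`link_baseline` — for every released record, scan every database
  row and count how many of the record's ``n`` pairs occur in that row
  (membership, not multiplicity).  ``O(m n p q)`` key comparisons.
* :func:`link_sorted` — flatten both tables into row-tagged key sequences,
  sort them, and count co-occurrences in a single merge over equal-key
  blocks, accumulating the sparse match-count matrix ``R``.
  ``O((mn + pq) log(mn + pq) + mp)``.

For each released record, all database rows attaining the maximum count are
reported.  A record whose unique best match is its true test is a true
positive; ties, misses and empty reports are false positives.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator, Mapping, Sequence

import numpy as np

from .simulator import ErgoTable, PatTable
from .transforms import ProjectionMode, canonical_values, time_components, timestamps_to_seconds

__all__ = [
    "LinkageError",
    "EmptyInputError",
    "UnsortedInputError",
    "OpCounter",
    "TaggedSequence",
    "MatchCounts",
    "MatchReport",
    "EvalResult",
    "build_tagged_sequences",
    "merge_count",
    "link_baseline",
    "link_sorted",
    "report_from_counts",
    "evaluate",
    "truth_map",
]


class LinkageError(ValueError):
    pass


class EmptyInputError(LinkageError):
    """Raised when either input table has no rows."""


class UnsortedInputError(LinkageError):
    """Raised when merge_count receives sequences that are not key-sorted."""


@dataclasses.dataclass
class OpCounter:
    """Instrumented operation counts for asymptotic-behaviour checks.

    ``key_comparisons`` accumulates the element comparisons each algorithm
    performs: the baseline counts its nested membership scans directly;
    the sort-merge path charges each comparison sort ``n ceil(log2 n)``
    (the standard comparison-sort cost) plus the merge-scan steps and
    emitted count updates it actually executes.
    """

    key_comparisons: int = 0

    def charge(self, n: int) -> None:
        self.key_comparisons += int(n)

    def charge_sort(self, n: int) -> None:
        if n > 1:
            self.key_comparisons += int(n) * math.ceil(math.log2(n))


# ---------------------------------------------------------------------------
# tagged key sequences
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TaggedSequence:
    """A flat sequence of canonical keys, each tagged with its source row.

    ``t`` is the projected time component (all zeros in value-only mode so
    the representation stays uniform), ``v`` the canonical integer value,
    ``row`` the source row index.
    """

    t: np.ndarray
    v: np.ndarray
    row: np.ndarray

    def __len__(self) -> int:
        return len(self.row)

    def sort(self, counter: OpCounter | None = None) -> "TaggedSequence":
        """Return a copy sorted by (key, row) — deterministic merge order."""
        order = np.lexsort((self.row, self.v, self.t))
        if counter is not None:
            counter.charge_sort(len(self.row))
        return TaggedSequence(self.t[order], self.v[order], self.row[order])

    def is_sorted(self) -> bool:
        t, v, r = self.t, self.v, self.row
        if len(r) < 2:
            return True
        dt = np.diff(t)
        dv = np.diff(v)
        dr = np.diff(r)
        ok = (dt > 0) | ((dt == 0) & ((dv > 0) | ((dv == 0) & (dr >= 0))))
        return bool(np.all(ok))

    def pairs(self) -> Iterator[tuple[tuple[int, int], int]]:
        """Iterate ((t, v), row) — convenience for small-scale tests."""
        for t, v, r in zip(self.t, self.v, self.row):
            yield (int(t), int(v)), int(r)


def _flatten_ergo(ergo: ErgoTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate all rows -> (epoch seconds, canonical values, row tags)."""
    ts = np.concatenate([timestamps_to_seconds(r.timestamps) for r in ergo.records])
    vs = np.concatenate([canonical_values(r.values, ergo.value_kind) for r in ergo.records])
    rows = np.repeat(np.arange(len(ergo.records), dtype=np.int64),
                     [r.n_readings for r in ergo.records])
    return ts, vs, rows


def _flatten_pat(pat: PatTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ts = np.concatenate([timestamps_to_seconds(r.timestamps) for r in pat.records])
    vs = np.concatenate([canonical_values(r.values, pat.value_kind) for r in pat.records])
    rows = np.repeat(np.arange(len(pat.records), dtype=np.int64),
                     [r.n_pairs for r in pat.records])
    return ts, vs, rows


def build_tagged_sequences(pat: PatTable, ergo: ErgoTable,
                           mode: ProjectionMode = ProjectionMode.DATETIME,
                           ) -> tuple[TaggedSequence, TaggedSequence]:
    """Flatten both tables into row-tagged canonical key sequences.

    The released-table sequence S1 keeps every pair (``m*n`` entries); the
    database sequence S2 de-duplicates repeated keys *within* a row, because
    a pair either occurs in a row or it does not — membership counting, so a
    key repeated inside one row must not inflate that row's count.
    """
    _check_kinds(pat, ergo)
    mode = ProjectionMode(mode)
    t1, v1, r1 = _flatten_pat(pat)
    t2, v2, r2 = _flatten_ergo(ergo)
    tc1 = time_components(t1, mode)
    tc2 = time_components(t2, mode)
    if tc1 is None:
        tc1 = np.zeros_like(v1)
        tc2 = np.zeros_like(v2)
    s1 = TaggedSequence(tc1, v1, r1)
    s2 = _dedup_within_rows(TaggedSequence(tc2, v2, r2))
    return s1, s2


def _dedup_within_rows(seq: TaggedSequence) -> TaggedSequence:
    """Drop duplicate (row, key) entries, preserving (row, key) order."""
    if len(seq) == 0:
        return seq
    order = np.lexsort((seq.v, seq.t, seq.row))
    t, v, r = seq.t[order], seq.v[order], seq.row[order]
    keep = np.empty(len(r), dtype=bool)
    keep[0] = True
    keep[1:] = (np.diff(r) != 0) | (np.diff(t) != 0) | (np.diff(v) != 0)
    return TaggedSequence(t[keep], v[keep], r[keep])


def _check_kinds(pat: PatTable, ergo: ErgoTable) -> None:
    if pat.value_kind != ergo.value_kind:
        raise LinkageError(
            f"value kinds differ ({pat.value_kind!r} vs {ergo.value_kind!r}); "
            "apply transforms to both tables symmetrically")


# ---------------------------------------------------------------------------
# match counts (the sparse matrix R)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MatchCounts:
    """Sparse (released row i, database row k) -> shared-pair count.

    Coordinate form sorted by (i, k); absent entries mean zero.  Kept sparse
    because a dense m × p matrix is prohibitive at realistic scale while the
    merge only ever touches equal-key blocks.
    """

    m: int
    p: int
    pat_rows: np.ndarray
    ergo_rows: np.ndarray
    counts: np.ndarray

    @property
    def nnz(self) -> int:
        return len(self.counts)

    def get(self, i: int, k: int) -> int:
        lo = np.searchsorted(self.pat_rows, i, side="left")
        hi = np.searchsorted(self.pat_rows, i, side="right")
        j = lo + np.searchsorted(self.ergo_rows[lo:hi], k, side="left")
        if j < hi and self.ergo_rows[j] == k:
            return int(self.counts[j])
        return 0

    def as_dict(self) -> dict[tuple[int, int], int]:
        return {(int(i), int(k)): int(c)
                for i, k, c in zip(self.pat_rows, self.ergo_rows, self.counts)}


def _encode_keys(s1: TaggedSequence, s2: TaggedSequence) -> tuple[np.ndarray, np.ndarray]:
    """Pack (t, v) pairs of both sequences into order-preserving int64 scalars."""
    if len(s1) == 0 or len(s2) == 0:
        return s1.v.copy(), s2.v.copy()
    t0 = min(int(s1.t.min()), int(s2.t.min()))
    v0 = min(int(s1.v.min()), int(s2.v.min()))
    vspan = max(int(s1.v.max()), int(s2.v.max())) - v0 + 1
    tspan = max(int(s1.t.max()), int(s2.t.max())) - t0 + 1
    if tspan * vspan >= 2 ** 62:
        raise LinkageError("key range too large to encode")
    e1 = (s1.t - t0) * vspan + (s1.v - v0)
    e2 = (s2.t - t0) * vspan + (s2.v - v0)
    return e1, e2


def _block_ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenated index ranges [starts[j], starts[j]+counts[j]) per block."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    reps = np.repeat(np.arange(len(starts), dtype=np.int64), counts)
    offs = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(counts) - counts, counts)
    return starts[reps] + offs


_PAIR_CHUNK = 8_000_000   # cross-join pairs materialized per merge chunk
_DENSE_LIMIT = 2 ** 28    # accumulate counts densely when m*p fits this budget


def merge_count(s1: TaggedSequence, s2: TaggedSequence,
                m: int | None = None, p: int | None = None,
                counter: OpCounter | None = None) -> MatchCounts:
    """Single merge over two key-sorted sequences -> sparse count matrix.

    For every equal-key block, each (released tag i, database tag k)
    combination in the block increments ``count(i, k)``; the result equals
    brute-force nested membership counting.  Raises
    :class:`UnsortedInputError` if either input violates the sort contract.
    """
    if not s1.is_sorted() or not s2.is_sorted():
        raise UnsortedInputError("merge_count requires sequences sorted by (key, row)")
    if m is None:
        m = int(s1.row.max()) + 1 if len(s1) else 0
    if p is None:
        p = int(s2.row.max()) + 1 if len(s2) else 0

    empty = MatchCounts(m, p, np.empty(0, np.int64), np.empty(0, np.int64),
                        np.empty(0, np.int64))
    if len(s1) == 0 or len(s2) == 0:
        return empty

    e1, e2 = _encode_keys(s1, s2)
    u1, starts1, c1 = np.unique(e1, return_index=True, return_counts=True)
    u2, starts2, c2 = np.unique(e2, return_index=True, return_counts=True)
    common, i1, i2 = np.intersect1d(u1, u2, assume_unique=True, return_indices=True)
    if counter is not None:
        counter.charge(len(u1) + len(u2))  # two-pointer merge scan
    if len(common) == 0:
        return empty

    b1s, b1c = starts1[i1], c1[i1]
    b2s, b2c = starts2[i2], c2[i2]
    npairs = b1c * b2c
    if counter is not None:
        counter.charge(int(npairs.sum()))  # count updates emitted

    # chunk the cross-join over common keys to bound peak memory
    bounds = np.concatenate(([0], np.cumsum(npairs)))
    dense = np.zeros(m * p, dtype=np.int32) if m * p <= _DENSE_LIMIT else None
    enc_chunks: list[np.ndarray] = []
    cnt_chunks: list[np.ndarray] = []
    start_key = 0
    nkeys = len(common)
    while start_key < nkeys:
        end_key = start_key + 1
        while end_key < nkeys and bounds[end_key + 1] - bounds[start_key] <= _PAIR_CHUNK:
            end_key += 1
        sel = slice(start_key, end_key)
        pat_idx, ergo_idx = _cross_join(s1.row, s2.row,
                                        b1s[sel], b1c[sel], b2s[sel], b2c[sel])
        enc = pat_idx * np.int64(p) + ergo_idx
        del pat_idx, ergo_idx
        enc.sort()
        uenc, ucnt = _run_lengths(enc)
        del enc
        if dense is not None:
            dense[uenc] += ucnt.astype(np.int32)  # uenc is unique within the chunk
        else:
            enc_chunks.append(uenc)
            cnt_chunks.append(ucnt)
        start_key = end_key

    if dense is not None:
        uenc = np.flatnonzero(dense)
        cnt = dense[uenc].astype(np.int64)
    else:
        enc_all = np.concatenate(enc_chunks)
        cnt_all = np.concatenate(cnt_chunks)
        if len(enc_chunks) > 1:
            order = np.argsort(enc_all, kind="stable")
            enc_all, cnt_all = enc_all[order], cnt_all[order]
            uenc, first = np.unique(enc_all, return_index=True)
            cnt = np.add.reduceat(cnt_all, first)
        else:
            uenc, cnt = enc_all, cnt_all
    return MatchCounts(m, p, uenc // p, uenc % p, cnt)


def _run_lengths(sorted_arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u, first = np.unique(sorted_arr, return_index=True)
    counts = np.diff(np.concatenate((first, [len(sorted_arr)])))
    return u, counts


def _cross_join(rows1: np.ndarray, rows2: np.ndarray,
                b1s: np.ndarray, b1c: np.ndarray,
                b2s: np.ndarray, b2c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (row1, row2) combinations within each equal-key block pair."""
    flat1 = rows1[_block_ranges(b1s, b1c)]          # blocks of S1, concatenated
    pat_idx = np.repeat(flat1, np.repeat(b2c, b1c))  # each S1 entry × its S2 block size
    npairs = b1c * b2c
    total = int(npairs.sum())
    pos = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(npairs) - npairs, npairs)
    within2 = pos % np.repeat(b2c, npairs)
    ergo_idx = rows2[np.repeat(b2s, npairs) + within2]
    return pat_idx, ergo_idx


# ---------------------------------------------------------------------------
# reports and evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MatchReport:
    """Per released record: best shared-pair count and the rows attaining it.

    ``argmax[i]`` is a sorted array of database row indices; empty when the
    record shares no pair with any row (max_count 0) — reporting "all rows
    tied at zero" would be meaningless.
    """

    m: int
    p: int
    max_counts: np.ndarray
    argmax: list[np.ndarray]

    def argmax_sets(self) -> list[frozenset[int]]:
        return [frozenset(int(k) for k in rows) for rows in self.argmax]


def report_from_counts(counts: MatchCounts) -> MatchReport:
    max_counts = np.zeros(counts.m, dtype=np.int64)
    argmax: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(counts.m)]
    if counts.nnz:
        rows_present, first = np.unique(counts.pat_rows, return_index=True)
        row_max = np.maximum.reduceat(counts.counts, first)
        max_counts[rows_present] = row_max
        best = counts.counts == max_counts[counts.pat_rows]
        bi, bk = counts.pat_rows[best], counts.ergo_rows[best]
        split = np.searchsorted(bi, np.arange(counts.m + 1))
        for i in range(counts.m):
            if split[i + 1] > split[i]:
                argmax[i] = bk[split[i]:split[i + 1]]
    return MatchReport(counts.m, counts.p, max_counts, argmax)


def _validate_nonempty(pat: PatTable, ergo: ErgoTable) -> None:
    if len(pat) == 0 or len(ergo) == 0:
        raise EmptyInputError("both tables must contain at least one row")


def link_sorted(pat: PatTable, ergo: ErgoTable,
                mode: ProjectionMode = ProjectionMode.DATETIME,
                counter: OpCounter | None = None) -> MatchReport:
    """Sort-merge linkage: sort both tagged sequences, merge, report argmax."""
    _validate_nonempty(pat, ergo)
    s1, s2 = build_tagged_sequences(pat, ergo, mode)
    s1 = s1.sort(counter)
    s2 = s2.sort(counter)
    counts = merge_count(s1, s2, m=len(pat), p=len(ergo), counter=counter)
    return report_from_counts(counts)


def link_baseline(pat: PatTable, ergo: ErgoTable,
                  mode: ProjectionMode = ProjectionMode.DATETIME,
                  counter: OpCounter | None = None) -> MatchReport:
    """Quadratic nested-scan linkage; output-identical to :func:`link_sorted`.

    For each released record and each of its pairs, scan every reading of
    every database row for an exact key match (an indicator matrix D over
    rows × pairs, reduced to per-row counts E), then report the argmax rows.
    """
    _validate_nonempty(pat, ergo)
    _check_kinds(pat, ergo)
    mode = ProjectionMode(mode)

    t2, v2, _ = _flatten_ergo(ergo)
    tc2 = time_components(t2, mode)
    t1, v1, _ = _flatten_pat(pat)
    tc1 = time_components(t1, mode)
    if tc1 is None:
        tc1, tc2 = np.zeros_like(v1), np.zeros_like(v2)
    e1, e2 = _encode_keys(TaggedSequence(tc1, v1, np.zeros_like(v1)),
                          TaggedSequence(tc2, v2, np.zeros_like(v2)))

    p = len(ergo)
    q_per_row = np.asarray([r.n_readings for r in ergo.records])
    row_starts = np.concatenate(([0], np.cumsum(q_per_row)[:-1]))
    n = pat.n_pairs
    pat_keys = e1.reshape(len(pat), n)

    m = len(pat)
    max_counts = np.zeros(m, dtype=np.int64)
    argmax: list[np.ndarray] = []
    for i in range(m):
        E = np.zeros(p, dtype=np.int64)
        for j in range(n):
            hits = e2 == pat_keys[i, j]          # scan every reading of every row
            if counter is not None:
                counter.charge(len(e2))
            D_ij = np.bitwise_or.reduceat(hits, row_starts)  # pair j found in row k?
            E += D_ij
        best = int(E.max())
        if best == 0:
            argmax.append(np.empty(0, dtype=np.int64))
        else:
            max_counts[i] = best
            argmax.append(np.flatnonzero(E == best).astype(np.int64))
    return MatchReport(m, p, max_counts, argmax)


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EvalResult:
    """Linkage quality: a record is a true positive iff its argmax set is
    exactly the singleton of its true row; ties, misses and empty reports
    are false positives, so TP + FP always equals the number of records."""

    tp: int
    fp: int

    @property
    def m(self) -> int:
        return self.tp + self.fp

    @property
    def fpr(self) -> float:
        return self.fp / self.m

    @property
    def accuracy(self) -> float:
        return self.tp / self.m


def evaluate(report: MatchReport, truth: Mapping[int, int] | Sequence[int]) -> EvalResult:
    """Score a report against ``truth`` (released row -> true database row)."""
    tp = 0
    for i in range(report.m):
        try:
            true_row = truth[i]
        except (KeyError, IndexError):
            raise LinkageError(f"ground truth missing for released row {i}") from None
        rows = report.argmax[i]
        if len(rows) == 1 and int(rows[0]) == int(true_row):
            tp += 1
    return EvalResult(tp=tp, fp=report.m - tp)


def truth_map(pat: PatTable, ergo: ErgoTable) -> dict[int, int]:
    """Released row index -> database row index, via the hidden true_test_id."""
    by_test = {rec.test_id: k for k, rec in enumerate(ergo.records)}
    out: dict[int, int] = {}
    for i, rec in enumerate(pat.records):
        if rec.true_test_id is None:
            raise LinkageError(f"released record {i} carries no ground truth")
        if rec.true_test_id not in by_test:
            raise LinkageError(f"true test {rec.true_test_id} absent from database")
        out[i] = by_test[rec.true_test_id]
    return out
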