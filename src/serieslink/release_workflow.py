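"""Privacy-preserving secondary-use release workflow.

A data holder wants to give an approved research team raw time-series
records plus a minimal identifying table, without exposing original patient
identifiers:

1. generate fresh random pseudonymous patient IDs (a bijection kept only by
   the holder);
2. optionally copy the minimal clinical attributes the study needs, keyed
   by the new IDs (opaque pass-through here — no clinical semantics);
3. restrict the time-series database to the study's patients and strip
   patient identifiers from it;
4. sample a few (timestamp, value) pairs per test, attach them to the
   pseudonymous ID, and — optionally — verify by self-linkage that the
   release links back with zero false positives, escalating the sample size
   until it does.

The released pair of tables lets the research team re-attach every test to
its (pseudonymous) patient with the sort-merge linker, while no
quasi-identifier ever leaves the holder.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulator import ErgoRecord, ErgoTable, PatRecord, PatTable
from .transforms import ProjectionMode
from .linkage import evaluate, link_sorted, truth_map

__all__ = ["ReleaseBundle", "ReleaseError", "pseudonymize", "prepare_release"]


class ReleaseError(ValueError):
    pass


@dataclasses.dataclass
class ReleaseBundle:
    """Everything the workflow produces.

    ``pat_release`` and ``ergo_release`` are the two tables handed to the
    research team; ``id_map`` (original -> pseudonymous ID) stays with the
    data holder and is never released.
    """

    pat_release: PatTable
    ergo_release: ErgoTable
    id_map: dict[str, str]
    sample_size_used: int
    attributes: pd.DataFrame | None = None


def pseudonymize(patient_ids: Iterable[str], rng: np.random.Generator) -> dict[str, str]:
    """Fresh random 128-bit hex identifiers, bijective and disjoint from input."""
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ReleaseError("duplicate patient identifiers in input")
    taken = set(ids)
    mapping: dict[str, str] = {}
    for pid in ids:
        while True:
            new = bytes(rng.integers(0, 256, size=16, dtype=np.uint8)).hex()
            if new not in taken:
                break
        taken.add(new)
        mapping[pid] = new
    return mapping


def _sample_record(rec: ErgoRecord, size: int, released_id: str,
                   rng: np.random.Generator,
                   indices: Sequence[int] | None) -> PatRecord:
    if indices is not None and len(indices) == size:
        idx = np.asarray(indices, dtype=np.int64)
        if np.any((idx < 0) | (idx >= rec.n_readings)):
            raise ReleaseError(f"sampling index out of range for test {rec.test_id}")
    else:
        idx = np.sort(rng.choice(rec.n_readings, size=size, replace=False))
    return PatRecord(released_id=released_id,
                     timestamps=rec.timestamps[idx].copy(),
                     values=rec.values[idx].copy(),
                     true_test_id=rec.test_id)


def prepare_release(ergo: ErgoTable,
                    study_patients: Iterable[str],
                    initial_sample_size: int = 4,
                    verify: bool = True,
                    rng: np.random.Generator | None = None,
                    *,
                    indices: Sequence[int] | None = None,
                    mode: ProjectionMode = ProjectionMode.DATETIME,
                    attributes: pd.DataFrame | None = None) -> ReleaseBundle:
    """Run the full workflow and return the first robust bundle.

    ``indices`` pins the fixed-index sampling scheme (used when its length
    equals the current sample size); otherwise positions are drawn uniformly
    without replacement per test.  With ``verify`` on, the candidate release
    is self-linked with the sort-merge linker under ``mode`` and, while any
    false positive remains, the sample size is incremented by one and the
    sampling repeated.  Robustness means zero false positives.  The sample
    size is bounded by the shortest series; exceeding it raises
    :class:`ReleaseError`.
    """
    if rng is None:
        rng = np.random.default_rng()
    study = set(study_patients)
    known = ergo.patients()
    missing = study - known
    if missing:
        raise ReleaseError(f"patients absent from the database: {sorted(missing)[:5]}")
    if initial_sample_size < 1:
        raise ReleaseError("initial_sample_size must be >= 1")

    selected = [rec for rec in ergo.records if rec.true_patient_id in study]
    q_min = min(rec.n_readings for rec in selected)
    if initial_sample_size > q_min:
        raise ReleaseError(
            f"sample size {initial_sample_size} exceeds shortest series ({q_min} readings)")

    id_map = pseudonymize(sorted(study), rng)
    ergo_release = ErgoTable(
        [ErgoRecord(test_id=rec.test_id, true_patient_id=None,
                    timestamps=rec.timestamps, values=rec.values)
         for rec in selected],
        value_kind=ergo.value_kind)

    size = initial_sample_size
    while True:
        pat = PatTable(
            [_sample_record(rec, size, id_map[rec.true_patient_id], rng, indices)
             for rec in selected],
            value_kind=ergo.value_kind)
        if not verify:
            break
        report = link_sorted(pat, ergo_release, mode)
        # pat row i was sampled from ergo_release row i
        result = evaluate(report, {i: i for i in range(len(selected))})
        if result.fp == 0:
            break
        size += 1
        if size > q_min:
            raise ReleaseError(
                "verification never reached zero false positives even at the "
                "full series length; the release is not robust under this key")

    released_attrs = None
    if attributes is not None:
        released_attrs = attributes.copy()
        released_attrs.index = [id_map[i] for i in attributes.index]

    return ReleaseBundle(pat_release=pat, ergo_release=ergo_release,
                         id_map=id_map, sample_size_used=size,
                         attributes=released_attrs)
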