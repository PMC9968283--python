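"""Linkage algorithms: hand-enumerated cases, oracle equivalence, evaluation."""

import numpy as np
import pytest

from serieslink import (
    ErgoTable,
    PatTable,
    ProjectionMode,
    build_tagged_sequences,
    categorize_values,
    evaluate,
    link_baseline,
    link_sorted,
    merge_count,
    sample_pat,
    truncate_values,
    truth_map,
)
from serieslink.linkage import (
    EmptyInputError,
    LinkageError,
    TaggedSequence,
    UnsortedInputError,
)
from conftest import make_ergo, make_pat, oracle_counts, oracle_report, random_instance

MODES = list(ProjectionMode)


def _seq(entries):
    t = np.asarray([e[0] for e in entries], dtype=np.int64)
    v = np.asarray([e[1] for e in entries], dtype=np.int64)
    r = np.asarray([e[2] for e in entries], dtype=np.int64)
    return TaggedSequence(t, v, r)


def test_merge_count_hand_enumeration():
    # one released pair with key κ, found in database rows 0 and 1
    s1 = _seq([(5, 700, 0)])
    s2 = _seq([(5, 700, 0), (5, 700, 1)])
    counts = merge_count(s1, s2, m=1, p=2)
    assert counts.as_dict() == {(0, 0): 1, (0, 1): 1}
    assert counts.get(0, 0) == 1 and counts.get(0, 1) == 1


def test_merge_count_disjoint_keys_is_empty():
    s1 = _seq([(1, 700, 0), (2, 710, 0)])
    s2 = _seq([(3, 700, 0), (4, 710, 1)])
    counts = merge_count(s1, s2, m=1, p=2)
    assert counts.nnz == 0
    assert counts.get(0, 0) == 0


def test_merge_count_rejects_unsorted_input():
    unsorted = _seq([(9, 700, 0), (1, 700, 0)])
    with pytest.raises(UnsortedInputError):
        merge_count(unsorted, _seq([(1, 700, 0)]))


def test_tagged_sequence_sizes_and_within_row_dedup():
    pat = make_pat([[(0, 70.0), (60, 71.0), (120, 72.0), (180, 73.0)]] * 2)
    # two readings of row 0 share the same (date, value) once time is dropped
    ergo = make_ergo([[(0, 70.0), (3600, 70.0), (7200, 71.0)],
                      [(0, 70.0), (60, 71.0), (120, 72.0)]])
    s1, s2 = build_tagged_sequences(pat, ergo, ProjectionMode.DATETIME)
    assert len(s1) == 2 * 4
    assert len(s2) == 6
    _, s2_date = build_tagged_sequences(pat, ergo, ProjectionMode.DATE_ONLY)
    assert len(s2_date) == 5  # (date, 70.0) kept once for row 0
    # S1 row tags do not depend on the key projection
    for mode in MODES:
        s1_m, _ = build_tagged_sequences(pat, ergo, mode)
        assert np.array_equal(s1_m.row, s1.row)


def test_two_way_tie_is_reported_in_full():
    # released record shares 2 pairs with rows 0 and 2, only 1 with row 1
    ergo = make_ergo([
        [(0, 70.0), (1, 71.0), (2, 99.0)],
        [(0, 70.0), (10, 80.0), (11, 81.0)],
        [(0, 70.0), (1, 71.0), (3, 98.0)],
        [(50, 60.0), (51, 61.0), (52, 62.0)],
        [(60, 63.0), (61, 64.0), (62, 65.0)],
    ])
    pat = make_pat([[(0, 70.0), (1, 71.0), (7, 97.0)]])
    for linker in (link_baseline, link_sorted):
        report = linker(pat, ergo)
        assert report.max_counts[0] == 2
        assert report.argmax_sets()[0] == frozenset({0, 2})


def test_verbatim_sample_links_uniquely_with_full_count(small_cohort):
    ergo, _ = small_cohort
    pat = sample_pat(ergo, [0, 40, 80, 119])
    report = link_sorted(pat, ergo)
    truth = truth_map(pat, ergo)
    for i in range(len(pat)):
        assert report.max_counts[i] == 4  # all n pairs found in the true row
        assert truth[i] in report.argmax_sets()[i]


def test_record_matching_nothing_has_empty_argmax():
    ergo = make_ergo([[(0, 70.0), (1, 71.0)]])
    pat = make_pat([[(500, 99.0), (501, 98.0)]])
    for linker in (link_baseline, link_sorted):
        report = linker(pat, ergo)
        assert report.max_counts[0] == 0
        assert report.argmax_sets()[0] == frozenset()


def test_empty_inputs_are_rejected():
    ergo = make_ergo([[(0, 70.0)]])
    pat = make_pat([[(0, 70.0)]])
    for linker in (link_baseline, link_sorted):
        with pytest.raises(EmptyInputError):
            linker(PatTable([]), ergo)
        with pytest.raises(EmptyInputError):
            linker(pat, ErgoTable([]))


def test_mismatched_value_kinds_are_rejected():
    ergo = make_ergo([[(0, 70.0)]])
    pat = truncate_values(make_pat([[(0, 70.0)]]))
    with pytest.raises(LinkageError):
        link_sorted(pat, ergo)


@pytest.mark.parametrize("transform", [None, truncate_values, categorize_values])
def test_linkers_agree_with_each_other_and_the_oracle(transform):
    """Randomized small instances: both linkers equal the nested-loop oracle."""
    rng = np.random.default_rng(2024)
    for trial in range(12):
        pat, ergo = random_instance(rng)
        if transform is not None:
            pat, ergo = transform(pat), transform(ergo)
        mode = MODES[trial % len(MODES)]
        s1, s2 = build_tagged_sequences(pat, ergo, mode)
        counts = merge_count(s1.sort(), s2.sort(), m=len(pat), p=len(ergo))
        assert counts.as_dict() == oracle_counts(pat, ergo, mode)
        rb = link_baseline(pat, ergo, mode)
        rs = link_sorted(pat, ergo, mode)
        expected = oracle_report(pat, ergo, mode)
        for i, (best, rows) in enumerate(expected):
            assert rb.max_counts[i] == rs.max_counts[i] == best
            assert rb.argmax_sets()[i] == rs.argmax_sets()[i] == rows
            assert best <= pat.n_pairs


def test_coarsening_the_key_never_decreases_any_count():
    rng = np.random.default_rng(7)
    coarser_than = {
        ProjectionMode.DATETIME: [ProjectionMode.DATE_ONLY, ProjectionMode.TIME_ONLY,
                                  ProjectionMode.VALUE_ONLY],
        ProjectionMode.DATE_ONLY: [ProjectionMode.VALUE_ONLY],
        ProjectionMode.TIME_ONLY: [ProjectionMode.VALUE_ONLY],
    }
    for _ in range(10):
        pat, ergo = random_instance(rng)
        counts = {mode: oracle_counts(pat, ergo, mode) for mode in MODES}
        # sanity: implementation agrees (its own monotonicity follows)
        for mode in MODES:
            s1, s2 = build_tagged_sequences(pat, ergo, mode)
            assert merge_count(s1.sort(), s2.sort(),
                               m=len(pat), p=len(ergo)).as_dict() == counts[mode]
        for fine, coarse_list in coarser_than.items():
            for coarse in coarse_list:
                for key, c in counts[fine].items():
                    assert counts[coarse].get(key, 0) >= c


def test_evaluation_conventions():
    # all correct and unique -> accuracy 1, FP 0
    ergo = make_ergo([[(0, 70.0), (1, 71.0)], [(10, 80.0), (11, 81.0)]])
    pat = make_pat([[(0, 70.0), (1, 71.0)], [(10, 80.0), (11, 81.0)]],
                   true_tests=["T0", "T1"])
    report = link_sorted(pat, ergo)
    res = evaluate(report, truth_map(pat, ergo))
    assert (res.tp, res.fp) == (2, 0)
    assert res.accuracy == 1.0 and res.fpr == 0.0

    # a tie between the true row and one impostor counts as a false positive
    report.argmax[0] = np.asarray([0, 1])
    res = evaluate(report, {0: 0, 1: 1})
    assert (res.tp, res.fp) == (1, 1)
    assert res.tp + res.fp == len(pat)
    assert res.fpr + res.accuracy == 1.0

    # an empty argmax is a false positive too
    report.argmax[0] = np.empty(0, dtype=np.int64)
    report.argmax[1] = np.empty(0, dtype=np.int64)
    res = evaluate(report, {0: 0, 1: 1})
    assert (res.tp, res.fp) == (0, 2)


def test_one_tie_among_ten_gives_fpr_one_tenth(small_cohort):
    ergo, _ = small_cohort
    pat = sample_pat(ergo, [0, 40, 80, 119])
    pat = PatTable(pat.records[:10], value_kind=pat.value_kind)
    report = link_sorted(pat, ergo)
    truth = truth_map(pat, ergo)
    assert evaluate(report, truth).fp == 0
    report.argmax[3] = np.sort(np.asarray([truth[3], (truth[3] + 1) % len(ergo)]))
    res = evaluate(report, truth)
    assert (res.tp, res.fp) == (9, 1)
    assert res.fpr == pytest.approx(0.1)


def test_missing_truth_entry_names_the_row():
    ergo = make_ergo([[(0, 70.0)]])
    pat = make_pat([[(0, 70.0)], [(0, 70.0)]])
    report = link_sorted(pat, ergo)
    with pytest.raises(LinkageError, match="row 1"):
        evaluate(report, {0: 0})
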