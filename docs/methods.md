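# Methods

## Linkage model

Both linkers solve the same problem: for each released record (a row of
`PAT`, *n* canonicalized `(timestamp, value)` keys), find every database
row (a row of `ERGO`, *q* readings) containing the largest number of those
keys. Matching is **exact membership**: a key either occurs in a row or it
does not, so a key repeated inside one database row contributes at most
one to that row's count (the sort-merge path enforces this by
de-duplicating keys within each row before merging; the baseline's
per-row *any*-reduction gives the same semantics). A released record's own
duplicate keys, by contrast, each count — the count is "how many of my *n*
pairs are found", bounded by *n*.

Canonicalization removes floating-point equality from the picture: raw
heart-rate values carry exactly one fractional digit by construction, so
they are scaled to integers (`round(10·v)`) before comparison; truncated
tables compare integers, categorical tables compare letter indices 0–25.
Timestamps become integer epoch seconds, then the projection mode selects
the component: identity, days since epoch, seconds since midnight, or
nothing. Both tables must be transformed symmetrically; the linkers reject
mixed value kinds.

The sort order is `(key, source row)`, which makes the merge output
deterministic regardless of input order. The merge materializes the count
matrix `R` sparsely (coordinate form): dense `m × p` storage would be
several gigabytes at realistic scale while the merge only touches
equal-key blocks. Internally, when `m·p ≤ 2^28` the merge accumulates into
a transient dense `int32` buffer (fast, and at most 1 GiB), falling back to
chunked coordinate aggregation beyond that; cross-join chunks are capped
at 8 million pairs to bound peak memory under heavily colliding keys
(value-only mode at cohort scale produces tens of millions of nonzero
counts).

**Tie convention.** A record is a true positive only when its argmax set
is exactly the singleton of its true row; ties, wrong singletons and empty
reports are all false positives. This is the only convention under which
`TP + FP` equals the number of released records, which is how the
headline tallies are reported. A record matching nothing gets an *empty*
argmax set rather than "all rows tied at zero", which would be
meaningless and would hide the failure.

## Synthetic cohort

The generator emulates ergometric heart-rate tests: three equal phases
(warm-up, stress, recovery) of `phase_length` readings (default 300) at
1 Hz, i.e. 900 readings per test. Reading 0 equals the drawn initial heart
rate; each later reading advances by the active phase's slope; i.i.d.
Gaussian noise is added; values are rounded to 0.1 bpm and floored at
30 bpm so extreme noise draws cannot go non-physiological.

Defaults, drawn uniformly and independently per test:

| parameter | default range | units |
|---|---|---|
| initial heart rate | [60, 90] | bpm |
| warm-up slope | [0.05, 0.15] | bpm/s |
| stress slope | [0.10, 0.30] | bpm/s |
| recovery slope | [−0.30, −0.10] | bpm/s |
| noise sd | [0.5, 2.0] | bpm |
| first-test start | uniform over 2024-01-01 .. 2026-01-01 | s resolution |
| inter-test gap (same patient) | [1 h, 7 d] | s |

The start window and gap range are this package's choice of a realistic
outpatient testing cadence (a couple of tests per week at most); nothing
downstream is sensitive to them except *how often* two tests of one
patient fall on the same calendar date, which is exactly what makes the
`date_only` degradation visible. One patient's test windows are disjoint
by construction (sequential scheduling with gaps); different patients may
overlap freely — cross-patient overlap is what makes chance collisions
possible under coarsened keys.

What the simulator does **not** model: realistic heart-rate value
distributions (real resting/exercise values are not uniform), circadian
or fitness structure across a patient's tests, missing readings, device
quantization other than 0.1 bpm, or minute-level wearable data. Passing
tests therefore demonstrate the algorithmic properties (exactness of
full-key linkage, degradation ordering, equivalence and scaling of the two
linkers) under controlled conditions — not linkage rates on any particular
real dataset, whose collision rates depend on its value and timing
distributions.

## Chance-collision model

For *K* independent attributes, attribute *k* uniform over `m_k` levels,
two random patients agree on everything with probability
`p_all = ∏ 1/m_k`, and among *n* patients the expected number of fully
agreeing pairs is `C(n,2)·p_all`. Integer ranges count levels half-open
(`[60, 220)` → 160 — note an inclusive range would give 161); time of day
at second resolution has 86,400 levels. The model deliberately keeps the
uniformity and independence assumptions; it counts matching patient
*pairs* and is not an FP-count predictor for the dependent time-series
experiment.

## Release workflow

`prepare_release` pseudonymizes (fresh random 128-bit hex IDs, a bijection
retained only by the holder), filters the database to the study's
patients, strips patient IDs, samples `sample_size` pairs per test
(fixed indices when supplied, else uniform distinct positions), and — when
verification is on — self-links the candidate release and increments the
sample size by one until zero false positives remain ("robust" means
exactly that; no other criterion is applied). The loop is bounded by the
series length, at which point a `ReleaseError` reports that the chosen key
cannot be made robust. Clinical study attributes are passed through as an
opaque table re-keyed to the pseudonyms; no clinical semantics are
modelled.

## File formats

Long-format CSV throughout: `ergo.csv` (`test_id, reading_index,
timestamp, value`), `pat.csv` (`released_id, record_index, pair_index,
timestamp, value`) and `matches.csv` (`released_id, record_index,
max_count, matched_test_ids`). `record_index` is carried in `pat.csv`
because a pseudonymous patient ID is shared by all of that patient's
released records, so the spec'd columns alone cannot be grouped back into
records. `truth.csv` (`test_id, patient_id, released_id, record_index`)
is a holder/test-side artifact and is never part of a release.

## Numerical and scale choices

* Operation counting replaces wall-clock benchmarking for the complexity
  check: the baseline counter counts executed membership comparisons; the
  sort-merge counter charges each comparison sort `n·⌈log₂ n⌉` (the sort
  itself is delegated to `numpy.lexsort`, whose comparisons are not
  observable) plus the executed merge-scan steps and emitted count
  updates. Log-log slopes over cohorts of 1000/2000/4000 tests (30
  readings each) come out ≈ 2.0 vs ≈ 1.1.
* Study-scale tests run a 400 × 20 × 900 cohort (8,000 tests) for the
  sort-merge linker and 50 × 20 for the quadratic baseline; the generator
  contract check runs the full 1600 × 20 configuration once. These sizes
  keep the suite fast while leaving every effect of interest (exactness,
  degradation, scaling) clearly measurable.
* Letter coding is defined for values in `[0, 260)` and raises a range
  error outside; truncation requires non-negative values. Truncating
  before letter-coding changes nothing (`⌊⌊v⌋/10⌋ = ⌊v/10⌋` for v ≥ 0).

## Known limitations

* Exact-match linkage only: no fuzzy matching, edit distances, banded
  value tolerance or probabilistic (Fellegi–Sunter) weighting.
* In-memory only; no out-of-core sorting for databases beyond RAM.
* The chance model's uniformity assumption overstates key entropy for
  real physiological values; treat its numbers as optimistic bounds.
* Pseudonymization protects identifiers, not the time series themselves;
  the release workflow makes no formal k-anonymity or differential-privacy
  guarantee.
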