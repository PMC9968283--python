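"""Closed-form model for matches that occur purely by chance.

With ``K`` independent attributes, attribute ``k`` uniform over ``m_k``
equally likely levels, two random patients agree on attribute ``k`` with
probability ``1/m_k``, on all attributes with probability
``p_all = prod_k 1/m_k``, and among ``n`` patients the expected number of
fully matching pairs is ``C(n, 2) * p_all``.

This is the birthday-problem style calculation used to reason about how
many and how fine-grained the released attributes must be for linkage to be
robust: second-resolution time of day alone contributes 86,400 levels,
integer heart rate in [60, 220) contributes 160.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

__all__ = [
    "AttributeLevels",
    "ChanceMatchResult",
    "attribute_levels",
    "pair_match_prob",
    "expected_chance_matches",
    "chance_match",
]

#: number-of-levels per attribute
AttributeLevels = Sequence[int]

SECONDS_PER_DAY = 86400


@dataclasses.dataclass(frozen=True)
class ChanceMatchResult:
    p_all: float
    expected_matches: float


def attribute_levels(kind) -> int:
    """Number of equally likely levels for an attribute descriptor.

    Accepted descriptors:

    * ``(lo, hi)`` — an integer range, counted half-open as ``hi - lo``
      (so heart rate on ``[60, 220)`` has 160 levels, not 161);
    * ``"time-of-day-seconds"`` — 86,400 levels;
    * ``("calendar-date", start, end)`` — days in the half-open window.
    """
    if isinstance(kind, str):
        if kind.replace("_", "-") == "time-of-day-seconds":
            return SECONDS_PER_DAY
        raise ValueError(f"unknown attribute descriptor: {kind!r}")
    kind = tuple(kind)
    if len(kind) == 3 and kind[0] == "calendar-date":
        start = np.datetime64(kind[1], "D")
        end = np.datetime64(kind[2], "D")
        days = int((end - start) / np.timedelta64(1, "D"))
        if days <= 0:
            raise ValueError("calendar-date window must span at least one day")
        return days
    lo, hi = kind
    if hi <= lo:
        raise ValueError(f"empty integer range [{lo}, {hi})")
    return int(hi) - int(lo)


def _validate_levels(levels: AttributeLevels) -> list[int]:
    ms = [int(m) for m in levels]
    if not ms:
        raise ValueError("at least one attribute is required")
    if any(m < 1 for m in ms):
        raise ValueError("every attribute must have at least one level")
    return ms


def pair_match_prob(levels: AttributeLevels) -> float:
    """Probability that two random patients agree on every attribute."""
    ms = _validate_levels(levels)
    return float(math.prod(1.0 / m for m in ms))


def expected_chance_matches(n_patients: int, levels: AttributeLevels) -> float:
    """Expected number of fully agreeing pairs among ``n_patients``."""
    if n_patients < 2:
        raise ValueError("need at least two patients to form a pair")
    return math.comb(n_patients, 2) * pair_match_prob(levels)


def chance_match(n_patients: int, levels: AttributeLevels) -> ChanceMatchResult:
    return ChanceMatchResult(
        p_all=pair_match_prob(levels),
        expected_matches=expected_chance_matches(n_patients, levels),
    )
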