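"""Inversion of screening patterns into candidate GM events.

Given observed positive/negative qPCR screening results, find which single
events — or minimal mixes of up to three distinct events — would produce
exactly that pattern according to the pre-computed score store.  A score
of 2 counts as detected and 0 as not detected; the ambiguous score 1
("imperfect binding, detection empirically unpredictable") is handled by
policy:

* ``wildcard`` (default) — an imperfect pair satisfies a positive call
  and does not violate a negative call;
* ``as_positive`` — treated as detected everywhere;
* ``as_negative`` — treated as not detected everywhere.

A combination fits when every positive method detects at least one member
and no negative method detects any member.  Only minimal fitting sets are
reported (every fitting set's supersets also fit, so non-minimal output
would be unbounded noise).  The search runs on per-method detection
bit-vectors, one bit per event.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

from .models import FinderResult, ScreeningPattern
from .scoring import ScoreStore, build_matrix

__all__ = ["POLICIES", "fits", "find_events"]

POLICIES = ("wildcard", "as_positive", "as_negative")


def _detected_for_positive(score: int, policy: str) -> bool:
    return score == 2 or (score == 1 and policy in ("wildcard", "as_positive"))


def _violates_negative(score: int, policy: str) -> bool:
    return score == 2 or (score == 1 and policy == "as_positive")


def _check_policy(policy: str) -> None:
    if policy not in POLICIES:
        raise ValueError(f"unknown ambiguous-score policy {policy!r}")


def fits(
    pattern: ScreeningPattern,
    combo: Iterable[str],
    store: ScoreStore,
    ambiguous_policy: str = "wildcard",
) -> bool:
    """Does this event combination explain the pattern?

    Direct application of the fit definition; the empty pattern fits any
    combination vacuously.
    """
    _check_policy(ambiguous_policy)
    members = list(combo)
    for m in pattern.positives:
        if not any(
            _detected_for_positive(store.get(e, m).score, ambiguous_policy)
            for e in members
        ):
            return False
    for m in pattern.negatives:
        if any(
            _violates_negative(store.get(e, m).score, ambiguous_policy)
            for e in members
        ):
            return False
    return True


def find_events(
    pattern: ScreeningPattern,
    events: Iterable,
    store: ScoreStore,
    max_combo_size: int = 3,
    ambiguous_policy: str = "wildcard",
) -> FinderResult:
    """All minimal event combinations of size <= *max_combo_size* fitting
    the pattern.

    Events violating any negative method are excluded outright; over the
    remaining events, positive-method coverage is checked by OR-ing
    detection bit-vectors, size-ascending, skipping supersets of already
    accepted combinations (which guarantees minimality, since fitting is
    monotone once negative violators are removed).
    """
    _check_policy(ambiguous_policy)
    if max_combo_size < 1:
        raise ValueError("max_combo_size must be >= 1")
    event_ids = [getattr(e, "event_id", e) for e in events]

    # per-method detection bit-vectors, one bit per event
    pos_masks: list[int] = []
    for m in pattern.positives:
        mask = 0
        for i, e in enumerate(event_ids):
            if _detected_for_positive(store.get(e, m).score, ambiguous_policy):
                mask |= 1 << i
        pos_masks.append(mask)
    excluded = 0
    for m in pattern.negatives:
        for i, e in enumerate(event_ids):
            if _violates_negative(store.get(e, m).score, ambiguous_policy):
                excluded |= 1 << i

    allowed = [i for i in range(len(event_ids)) if not (excluded >> i) & 1]

    accepted_bits: list[int] = []
    accepted: list[frozenset[str]] = []
    for size in range(1, max_combo_size + 1):
        for combo in combinations(allowed, size):
            bits = 0
            for i in combo:
                bits |= 1 << i
            if any(a & bits == a for a in accepted_bits):
                continue  # superset of an already-minimal fit
            if all(mask & bits for mask in pos_masks):
                accepted_bits.append(bits)
                accepted.append(frozenset(event_ids[i] for i in combo))

    accepted.sort(key=lambda s: (len(s), tuple(sorted(s))))
    involved = sorted(set().union(*accepted)) if accepted else []
    excerpt = build_matrix(involved, pattern.method_ids, store)
    return FinderResult(combinations=accepted, matrix_excerpt=excerpt)
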