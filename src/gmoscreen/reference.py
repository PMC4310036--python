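"""Brute-force reference implementations used for validation.

The binding-site reference enumerates every explicit gap layout within the
gap budget — a layout is a multiset of deletion boundaries (template base
skipped between two query positions) and a set of inserted query positions
— and evaluates each layout at every template start from diagonal
prefix-sum tables.  This covers exactly the alignment space of the banded
DP in :mod:`gmoscreen.align` but by a structurally different route, so the
two act as independent cross-checks.

The finder reference enumerates all event subsets up to the requested size
and applies the fit definition directly.

These functions are quadratic-to-cubic in the inputs and meant for
fixtures and tests, not for production scoring.
"""

from __future__ import annotations

from itertools import combinations, combinations_with_replacement

import numpy as np

from .align import StartAlignment
from .models import BindingSite, ScreeningPattern
from .nucleotides import reverse_complement, sequence_mask
from .pcr import reduce_to_local_optima

__all__ = [
    "reference_binding_sites",
    "reference_find_events",
    "detection_sets",
]


def _layouts(L: int, max_gaps: int):
    """All gap layouts (deletion boundaries, inserted query positions)."""
    for nd in range(max_gaps + 1):
        for ni in range(max_gaps + 1 - nd):
            for dels in combinations_with_replacement(range(L + 1), nd):
                for ins in combinations(range(L), ni):
                    yield dels, ins


def _layout_segments(L: int, dels: tuple[int, ...], ins: tuple[int, ...]):
    """Ungapped segments of a layout as (q_start, q_end, offset) triples.

    ``offset`` is (template index) - (query index) - (start); it increases
    by one at each deletion boundary and decreases by one after each
    inserted query base.
    """
    events: list[tuple[int, int]] = []  # (position, +1 deletion / -1 insertion)
    for p in dels:
        events.append((p, +1))
    for p in ins:
        events.append((p, -1))
    # at equal positions apply deletions before the inserted base
    events.sort(key=lambda e: (e[0], -e[1]))

    segments = []
    off = 0
    q = 0
    for pos, kind in events:
        if kind == +1:  # deletion boundary before query position pos
            if pos > q:
                segments.append((q, pos, off))
                q = pos
            off += 1
        else:  # query base pos unaligned
            if pos > q:
                segments.append((q, pos, off))
            q = pos + 1
            off -= 1
    if q < L:
        segments.append((q, L, off))
    return segments


def _strand_candidates(
    qmask: np.ndarray, tmask: np.ndarray, max_gaps: int
) -> list[StartAlignment]:
    L = int(qmask.size)
    T = int(tmask.size)
    G = max_gaps
    n_starts = T - L + G + 1
    if n_starts <= 0:
        return []

    # diag[o][s, q] = 1 if query base q matches template position s+q+o
    pad = np.zeros(2 * G + 2, dtype=np.uint8)
    padded = np.concatenate([tmask, pad])
    cum: dict[int, np.ndarray] = {}
    starts = np.arange(n_starts)
    for o in range(-G, G + 1):
        t_idx = starts[:, None] + np.arange(L)[None, :] + o
        ok = (t_idx >= 0) & (t_idx < T)
        m = np.zeros((n_starts, L), dtype=np.int64)
        sel = np.clip(t_idx, 0, T + 2 * G)
        m[ok] = ((qmask[None, :] & padded[sel]) != 0).astype(np.int64)[ok]
        # cumulative over query axis, leading zero column for range sums
        cum[o] = np.concatenate(
            [np.zeros((n_starts, 1), dtype=np.int64), np.cumsum(m, axis=1)], axis=1
        )

    NEG = -(10**9)
    best_key = np.full(n_starts, NEG, dtype=np.int64)
    best_score = np.zeros(n_starts, dtype=np.int64)
    best_mm = np.zeros(n_starts, dtype=np.int64)
    best_g = np.zeros(n_starts, dtype=np.int64)
    best_d = np.zeros(n_starts, dtype=np.int64)

    for dels, ins in _layouts(L, G):
        g = len(dels) + len(ins)
        d = len(dels) - len(ins)
        matches = np.zeros(n_starts, dtype=np.int64)
        aligned = 0
        for a, b, off in _layout_segments(L, dels, ins):
            matches += cum[off][:, b] - cum[off][:, a]
            aligned += b - a
        mm = aligned - matches
        score = matches - mm - 2 * g
        valid = starts + L + d <= T
        key = np.where(valid, score * 64 - g * 8 - (d + G), NEG)
        better = key > best_key
        best_key[better] = key[better]
        best_score[better] = score[better]
        best_mm[better] = mm[better]
        best_g[better] = g
        best_d[better] = d

    out = []
    for s in range(n_starts):
        if best_key[s] <= NEG // 2:
            continue
        out.append(
            StartAlignment(
                start=s,
                end=s + L + int(best_d[s]),
                score=int(best_score[s]),
                mismatches=int(best_mm[s]),
                gap_bases=int(best_g[s]),
            )
        )
    return out


def reference_binding_sites(
    primer: str,
    template: str,
    max_mismatches: int = 2,
    max_gaps: int = 2,
    primer_role: str = "primer1",
) -> list[BindingSite]:
    """Binding sites by exhaustive gap-layout enumeration (both strands)."""
    primer = primer.upper()
    template = template.upper()
    tmask = sequence_mask(template)
    sites: list[BindingSite] = []
    for strand, query in (("plus", primer), ("minus", reverse_complement(primer))):
        cands = _strand_candidates(sequence_mask(query), tmask, max_gaps)
        passing = [a for a in cands if a.mismatches <= max_mismatches]
        for a in reduce_to_local_optima(passing):
            sites.append(
                BindingSite(primer_role, strand, a.start, a.end, a.mismatches, a.gap_bases)
            )
    sites.sort(key=lambda s: (s.start, s.end, s.strand))
    return sites


def detection_sets(
    scores: dict[tuple[str, str], int],
    event_ids: list[str],
    method_id: str,
    policy: str,
) -> tuple[set[str], set[str]]:
    """(events counting as detected for a positive call,
    events violating a negative call) for one method under a policy."""
    if policy not in ("wildcard", "as_positive", "as_negative"):
        raise ValueError(f"unknown ambiguous-score policy {policy!r}")
    pos, neg = set(), set()
    for e in event_ids:
        s = scores[(e, method_id)]
        detected_for_pos = s == 2 or (s == 1 and policy in ("wildcard", "as_positive"))
        violates_neg = s == 2 or (s == 1 and policy == "as_positive")
        if detected_for_pos:
            pos.add(e)
        if violates_neg:
            neg.add(e)
    return pos, neg


def reference_find_events(
    pattern: ScreeningPattern,
    event_ids: list[str],
    scores: dict[tuple[str, str], int],
    max_combo_size: int = 3,
    policy: str = "wildcard",
) -> list[frozenset[str]]:
    """Minimal fitting combinations by full subset enumeration."""

    pos_sets = {
        m: detection_sets(scores, event_ids, m, policy)[0] for m in pattern.positives
    }
    neg_sets = {
        m: detection_sets(scores, event_ids, m, policy)[1] for m in pattern.negatives
    }

    def fits(combo: frozenset[str]) -> bool:
        return all(combo & pos_sets[m] for m in pattern.positives) and not any(
            combo & neg_sets[m] for m in pattern.negatives
        )

    fitting = [
        frozenset(c)
        for size in range(1, max_combo_size + 1)
        for c in combinations(event_ids, size)
        if fits(frozenset(c))
    ]
    minimal = [
        s for s in fitting if not any(t < s for t in fitting)
    ]
    minimal.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return minimal
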