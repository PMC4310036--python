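"""Canonical semi-global alignment engine.

A primer (or probe) must align over its full length to a local window of
the template.  The canonical alignment of a given template start position
is the optimum, over all alignments using at most ``max_gaps`` gap bases
in total, of the score

    +1 per match, -1 per mismatch, -2 per gap base,

with ties broken by fewer gap bases, then by the smaller window end.
Matching is IUPAC-set intersection (degenerate codes are wildcards over
their sets).  Restricting the search space to the gap budget makes the
objective well defined and bandable, and the optimum never trades a
substitution for an insertion+deletion pair (cost -4 vs -2), so mismatch
counts cannot be smuggled under the gap budget.

The DP is banded over diagonal offset d = (template consumed) - (primer
consumed), |d| <= max_gaps, with the exact gap-base count g as part of the
state, and is vectorised with numpy across all template start positions at
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StartAlignment", "canonical_start_alignments"]

_NEG = -(2**30)


@dataclass(frozen=True)
class StartAlignment:
    """Canonical alignment of the full query at one template start."""

    start: int
    end: int
    score: int
    mismatches: int
    gap_bases: int


def canonical_start_alignments(
    query_mask: np.ndarray,
    template_mask: np.ndarray,
    max_gaps: int,
) -> list[StartAlignment]:
    """Canonical alignment for every template start position.

    Parameters are 4-bit IUPAC set masks (see
    :func:`gmoscreen.nucleotides.sequence_mask`).  Returns one
    :class:`StartAlignment` per start position that admits any alignment
    within the gap budget (no mismatch filtering here).
    """
    L = int(query_mask.size)
    T = int(template_mask.size)
    G = int(max_gaps)
    if L == 0:
        raise ValueError("empty query")
    n_starts = T - L + G + 1  # largest start still fits the shortest window
    if n_starts <= 0:
        return []

    # Match/mismatch scores M[i, t] for query base i against template
    # position t; right padding keeps slice lookups in range, padded
    # columns score as mismatches and the affected states are discarded
    # by the end <= T check below.
    pad = np.zeros(2 * G + 1, dtype=np.uint8)
    tmask = np.concatenate([template_mask, pad])
    inter = (query_mask[:, None] & tmask[None, :]) != 0
    M = np.where(inter, 1, -1).astype(np.int64)

    d_range = range(-G, G + 1)
    g_range = range(G + 1)

    def fresh() -> dict[tuple[int, int], np.ndarray]:
        return {
            (d, g): np.full(n_starts, _NEG, dtype=np.int64)
            for d in d_range
            for g in g_range
        }

    V = fresh()
    V[(0, 0)][:] = 0
    for k in range(1, G + 1):  # leading deletions (template bases skipped)
        V[(k, k)][:] = -2 * k

    for i in range(1, L + 1):
        new = fresh()
        for d in d_range:
            t0 = i - 1 + d  # template offset consumed by the diagonal move
            for g in g_range:
                best = new[(d, g)]
                if t0 >= 0:
                    np.maximum(best, V[(d, g)] + M[i - 1, t0 : t0 + n_starts], out=best)
                if g >= 1 and d + 1 <= G:  # insertion: query base i-1 unaligned
                    np.maximum(best, V[(d + 1, g - 1)] - 2, out=best)
        # deletions within the row, d ascending so chains propagate
        for g in g_range:
            if g == 0:
                continue
            for d in d_range:
                if d - 1 < -G:
                    continue
                np.maximum(new[(d, g)], new[(d - 1, g - 1)] - 2, out=new[(d, g)])
        V = new

    # Final selection per start: maximise (score, -gap_bases, -end).
    starts = np.arange(n_starts)
    keys = []
    metas = []
    for d in d_range:
        for g in g_range:
            score = V[(d, g)]
            valid = starts + L + d <= T
            key = np.where(valid, score * 64 - g * 8 - (d + G), _NEG)
            keys.append(key)
            metas.append((d, g))
    key_arr = np.stack(keys)
    best_idx = np.argmax(key_arr, axis=0)
    best_key = key_arr[best_idx, starts]

    out: list[StartAlignment] = []
    threshold = _NEG // 2
    for s in range(n_starts):
        if best_key[s] <= threshold:
            continue
        d, g = metas[best_idx[s]]
        score = int(V[(d, g)][s])
        # g = ins + del and d = del - ins, so ins is determined; with
        # matches + mismatches = L - ins and score = matches - mismatches
        # - 2 g, the mismatch count follows exactly.
        ins = (g - d) // 2
        mm = (L - ins - score - 2 * g) // 2
        out.append(
            StartAlignment(
                start=s, end=s + L + d, score=score, mismatches=mm, gap_bases=g
            )
        )
    return out
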