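"""In-silico PCR: approximate primer-site search and amplicon enumeration.

Mirrors the pre-computation stage of an electronic-PCR screen: each primer
is searched on both strands of a template under per-primer budgets of at
most 2 mismatches and 2 gap bases (defaults), and candidate amplicons are
enumerated for all three primer pairings — the intended forward/reverse
pair plus the two same-primer pairings, whose products fall outside the
assay's intent and are flagged downstream as warnings.
"""

from __future__ import annotations

from .align import StartAlignment, canonical_start_alignments
from .models import MIN_OLIGO_LEN, AmpliconHit, BindingSite, DetectionMethod, PCRParams
from .nucleotides import reverse_complement, sequence_mask

__all__ = ["find_binding_sites", "enumerate_amplicons", "reduce_to_local_optima"]


def reduce_to_local_optima(
    candidates: list[StartAlignment],
) -> list[StartAlignment]:
    """Suppress shifted echoes of stronger sites.

    A candidate is dropped iff a retained, strictly better-scoring
    candidate overlaps its interval.  Processing in decreasing score makes
    the retained set well defined by induction on score and independent of
    tie order (equal-scoring overlapping sites are all retained).
    """
    retained: list[StartAlignment] = []
    for c in sorted(candidates, key=lambda a: (-a.score, a.gap_bases, a.start)):
        if any(
            r.score > c.score and c.start < r.end and r.start < c.end
            for r in retained
        ):
            continue
        retained.append(c)
    return retained


def _strand_sites(
    query: str,
    template_mask,
    max_mismatches: int,
    max_gaps: int,
) -> list[StartAlignment]:
    aligns = canonical_start_alignments(sequence_mask(query), template_mask, max_gaps)
    passing = [a for a in aligns if a.mismatches <= max_mismatches]
    return reduce_to_local_optima(passing)


def find_binding_sites(
    primer: str,
    template: str,
    max_mismatches: int = 2,
    max_gaps: int = 2,
    primer_role: str = "primer1",
) -> list[BindingSite]:
    """All annealing sites of *primer* on both strands of *template*.

    Minus-strand sites are located by searching the reverse complement of
    the primer on the plus strand and are reported in plus-strand
    coordinates.  Each reported site carries the mismatch and gap-base
    counts of its canonical alignment; both stay within the budgets.
    """
    if max_mismatches < 0 or max_gaps < 0:
        raise ValueError("edit budgets must be non-negative")
    primer = primer.upper()
    if len(primer) < MIN_OLIGO_LEN:
        raise ValueError(f"primer must be at least {MIN_OLIGO_LEN} nt")
    template = template.upper()
    tmask = sequence_mask(template)

    sites: list[BindingSite] = []
    for strand, query in (("plus", primer), ("minus", reverse_complement(primer))):
        for a in _strand_sites(query, tmask, max_mismatches, max_gaps):
            sites.append(
                BindingSite(
                    primer_role=primer_role,
                    strand=strand,
                    start=a.start,
                    end=a.end,
                    mismatches=a.mismatches,
                    gap_bases=a.gap_bases,
                )
            )
    sites.sort(key=lambda s: (s.start, s.end, s.strand))
    return sites


_KIND_ORDER = {"p1_p2": 0, "p1_p1": 1, "p2_p2": 2}


def enumerate_amplicons(
    method: DetectionMethod,
    template: str,
    event_id: str = "",
    sequence_index: int = 0,
    params: PCRParams = PCRParams(),
) -> list[AmpliconHit]:
    """Candidate amplicons of *method* on *template*, all three pairings.

    Every convergent (plus-strand site, minus-strand site) pair whose
    end-to-end span — primer footprints included — lies within the
    amplicon-length bounds yields one hit.  Same-primer pairings are
    included (``pair_kind`` p1_p1 / p2_p2); a single footprint pairing
    with itself is not an amplicon and is excluded.
    """
    sites1 = find_binding_sites(
        method.primer1, template, params.max_mismatches, params.max_gaps, "primer1"
    )
    sites2 = find_binding_sites(
        method.primer2, template, params.max_mismatches, params.max_gaps, "primer2"
    )
    plus1 = [s for s in sites1 if s.strand == "plus"]
    minus1 = [s for s in sites1 if s.strand == "minus"]
    plus2 = [s for s in sites2 if s.strand == "plus"]
    minus2 = [s for s in sites2 if s.strand == "minus"]

    pairings = [
        ("p1_p2", plus1, minus2),
        ("p1_p2", plus2, minus1),
        ("p1_p1", plus1, minus1),
        ("p2_p2", plus2, minus2),
    ]

    hits: list[AmpliconHit] = []
    seen: set[tuple] = set()
    for kind, lefts, rights in pairings:
        for left in lefts:
            for right in rights:
                if kind != "p1_p2" and left.interval == right.interval:
                    continue  # one footprint priming on itself
                if left.start >= right.end:
                    continue  # not convergent
                length = right.end - left.start
                if not (params.amplicon_min <= length <= params.amplicon_max):
                    continue
                key = (kind, left.primer_role, left.interval, right.interval)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(
                    AmpliconHit(
                        event_id=event_id,
                        sequence_index=sequence_index,
                        method_id=method.method_id,
                        pair_kind=kind,
                        left_site=left,
                        right_site=right,
                        start=left.start,
                        end=right.end,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end, _KIND_ORDER[h.pair_kind]))
    return hits
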