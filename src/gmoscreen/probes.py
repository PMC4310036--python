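"""TaqMan probe binding classification.

A probe can hybridise to either strand of a candidate amplicon, so the
alignment is run twice — against the extracted amplicon and against its
reverse complement — and the better alignment decides.  The probe must be
covered end-to-end (a partial local alignment cannot report meaningful
mismatch budgets); within full coverage the same canonical objective and
budgets as for primer annealing apply:

* ``perfect``   — full-length exact hybridisation (0 mismatches, 0 gaps);
* ``imperfect`` — covered, with at most 2 mismatches and 2 gap bases;
* ``none``      — everything else (the hit is treated as a non-detection,
  since TaqMan chemistry needs probe hydrolysis for a signal).
"""

from __future__ import annotations

from .align import canonical_start_alignments
from .models import MIN_OLIGO_LEN, ProbeAlignment
from .nucleotides import reverse_complement, sequence_mask

__all__ = ["align_probe"]


def align_probe(
    probe: str,
    amplicon_seq: str,
    max_mismatches: int = 2,
    max_gaps: int = 2,
) -> ProbeAlignment:
    """Classify probe binding against one amplicon sequence.

    Returns the higher-scoring of the two orientations; the result is
    invariant to which orientation of the amplicon is passed in.
    """
    if not amplicon_seq:
        raise ValueError("empty amplicon")
    probe = probe.upper()
    if len(probe) < MIN_OLIGO_LEN:
        raise ValueError(f"probe must be at least {MIN_OLIGO_LEN} nt")
    amplicon_seq = amplicon_seq.upper()
    pmask = sequence_mask(probe)

    best = None  # (score, -g, -mm, plus-preferred, -start), alignment, strand
    for strand, amp in (
        ("plus", amplicon_seq),
        ("minus", reverse_complement(amplicon_seq)),
    ):
        for a in canonical_start_alignments(pmask, sequence_mask(amp), max_gaps):
            key = (
                a.score,
                -a.gap_bases,
                -a.mismatches,
                1 if strand == "plus" else 0,
                -a.start,
            )
            if best is None or key > best[0]:
                best = (key, a, strand)

    if best is None:  # amplicon too short to ever cover the probe
        return ProbeAlignment(
            strand="plus",
            mismatches=None,
            gap_bases=None,
            covered=False,
            classification="none",
        )

    _, aln, strand = best
    if aln.mismatches == 0 and aln.gap_bases == 0:
        cls = "perfect"
    elif aln.mismatches <= max_mismatches:  # gap budget holds by construction
        cls = "imperfect"
    else:
        cls = "none"
    return ProbeAlignment(
        strand=strand,
        mismatches=aln.mismatches,
        gap_bases=aln.gap_bases,
        covered=True,
        classification=cls,
    )
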