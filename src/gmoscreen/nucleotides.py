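"""IUPAC nucleotide utilities.

Degenerate codes are represented internally as 4-bit sets over {A, C, G, T};
two codes *match* when their base sets intersect.  This is the convention
used throughout the package: a degenerate base in a primer or probe is a
wildcard over its set and contributes zero mismatches when it can pair with
the template base.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IUPAC_CODES",
    "iupac_match",
    "reverse_complement",
    "sequence_mask",
    "validate_iupac",
]

_A, _C, _G, _T = 1, 2, 4, 8

#: IUPAC code -> 4-bit base set (bit order A, C, G, T).
IUPAC_CODES: dict[str, int] = {
    "A": _A,
    "C": _C,
    "G": _G,
    "T": _T,
    "R": _A | _G,
    "Y": _C | _T,
    "S": _C | _G,
    "W": _A | _T,
    "K": _G | _T,
    "M": _A | _C,
    "B": _C | _G | _T,
    "D": _A | _G | _T,
    "H": _A | _C | _T,
    "V": _A | _C | _G,
    "N": _A | _C | _G | _T,
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

# Fast lookup table: byte -> bitmask (0 for non-IUPAC bytes).
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _code, _bits in IUPAC_CODES.items():
    _MASK_TABLE[ord(_code)] = _bits
    _MASK_TABLE[ord(_code.lower())] = _bits

_COMP_TRANS = str.maketrans(_COMPLEMENT)


def validate_iupac(seq: str, *, context: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first non-IUPAC character in *seq*."""
    for pos, ch in enumerate(seq):
        if ch.upper() not in IUPAC_CODES:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {pos + 1} in {context}"
            )


def iupac_match(code_a: str, code_b: str) -> bool:
    """True iff the base sets denoted by two IUPAC codes intersect.

    Symmetric and reflexive; e.g. ``iupac_match('R', 'A')`` is True
    ({A,G} contains A) while ``iupac_match('R', 'Y')`` is False.
    """
    try:
        a = IUPAC_CODES[code_a.upper()]
        b = IUPAC_CODES[code_b.upper()]
    except (KeyError, AttributeError):
        bad = code_a if not isinstance(code_a, str) or code_a.upper() not in IUPAC_CODES else code_b
        raise ValueError(f"non-IUPAC code {bad!r}") from None
    return (a & b) != 0


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (R<->Y, S<->S, W<->W, K<->M,
    B<->V, D<->H, N<->N).  An involution: applying it twice returns the input.
    """
    seq = seq.upper()
    validate_iupac(seq)
    return seq.translate(_COMP_TRANS)[::-1]


def sequence_mask(seq: str) -> np.ndarray:
    """Encode a sequence as an array of 4-bit base-set masks (uint8)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_TABLE[raw]
    if (masks == 0).any():
        bad = int(np.nonzero(masks == 0)[0][0])
        raise ValueError(f"non-IUPAC character {seq[bad]!r} at position {bad + 1}")
    return masks
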