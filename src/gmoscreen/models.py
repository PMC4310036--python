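"""Domain types for the in-silico screening pipeline.

The objects mirror the stages of the simulation: a validated PCR assay
(:class:`DetectionMethod`) is searched against the template sequences of a
transformation event (:class:`GMOEvent`); approximate primer annealing
positions (:class:`BindingSite`) are paired into candidate amplicons
(:class:`AmpliconHit`); TaqMan probe hybridisation is classified
(:class:`ProbeAlignment`); and each method x event pair collapses to a
pre-computable 0/1/2 score (:class:`PairScore`) that feeds the screening
matrix (:class:`MatrixView`) and the pattern-inversion finder
(:class:`ScreeningPattern` / :class:`FinderResult`).

Coordinates are 0-based half-open internally; rendered reports use 1-based
inclusive positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .nucleotides import IUPAC_CODES, validate_iupac

__all__ = [
    "METHOD_TYPES",
    "PAIR_KINDS",
    "DetectionMethod",
    "GMOEvent",
    "BindingSite",
    "AmpliconHit",
    "ProbeAlignment",
    "PairScore",
    "PCRParams",
    "MatrixView",
    "ScreeningPattern",
    "FinderResult",
]

METHOD_TYPES = (
    "event_specific",
    "construct_specific",
    "element_specific",
    "taxon_specific",
)

#: intended primer pairing plus the two self-pairings also simulated
PAIR_KINDS = ("p1_p2", "p1_p1", "p2_p2")

MIN_OLIGO_LEN = 10

_TEMPLATE_OK = frozenset(IUPAC_CODES)


def _check_oligo(seq: str, what: str) -> None:
    if not seq or len(seq) < MIN_OLIGO_LEN:
        raise ValueError(f"{what} must be at least {MIN_OLIGO_LEN} nt, got {seq!r}")
    validate_iupac(seq, context=what)


@dataclass(frozen=True)
class DetectionMethod:
    """A validated qPCR assay: two primers and an optional TaqMan probe."""

    method_id: str
    method_type: str
    target_name: str
    primer1: str
    primer2: str
    probe: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.method_id:
            raise ValueError("method_id must be non-empty")
        if self.method_type not in METHOD_TYPES:
            raise ValueError(
                f"unknown method_type {self.method_type!r} for {self.method_id}; "
                f"expected one of {METHOD_TYPES}"
            )
        object.__setattr__(self, "primer1", self.primer1.upper())
        object.__setattr__(self, "primer2", self.primer2.upper())
        _check_oligo(self.primer1, f"primer1 of {self.method_id}")
        _check_oligo(self.primer2, f"primer2 of {self.method_id}")
        if self.probe == "":
            object.__setattr__(self, "probe", None)
        if self.probe is not None:
            object.__setattr__(self, "probe", self.probe.upper())
            _check_oligo(self.probe, f"probe of {self.method_id}")

    @property
    def has_probe(self) -> bool:
        return self.probe is not None


@dataclass(frozen=True)
class GMOEvent:
    """A transformation event with one or more template sequences.

    Retransformed and stacked events carry several sequences under one
    event identifier; scoring pools hits over all of them.
    """

    event_id: str
    sequences: tuple[str, ...]
    sequence_labels: tuple[str, ...] = ()
    taxon: str = ""

    def __post_init__(self) -> None:
        if not self.event_id:
            raise ValueError("event_id must be non-empty")
        seqs = tuple(s.upper() for s in self.sequences)
        if not seqs:
            raise ValueError(f"event {self.event_id} has no sequences")
        for i, s in enumerate(seqs):
            if not s:
                raise ValueError(f"event {self.event_id} sequence {i} is empty")
            validate_iupac(s, context=f"event {self.event_id} sequence {i}")
        object.__setattr__(self, "sequences", seqs)
        labels = tuple(self.sequence_labels)
        if not labels:
            labels = tuple(f"seq{i + 1}" for i in range(len(seqs)))
        if len(labels) != len(seqs):
            raise ValueError(
                f"event {self.event_id}: {len(labels)} labels for {len(seqs)} sequences"
            )
        object.__setattr__(self, "sequence_labels", labels)


@dataclass(frozen=True)
class BindingSite:
    """One annealed primer footprint on a template.

    ``start``/``end`` delimit the covered template interval in plus-strand
    coordinates regardless of ``strand``; ``gap_bases`` counts inserted plus
    deleted bases of the canonical alignment (not gap openings).
    """

    primer_role: str  # "primer1" | "primer2"
    strand: str  # "plus" | "minus"
    start: int
    end: int
    mismatches: int
    gap_bases: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def edits(self) -> int:
        return self.mismatches + self.gap_bases

    @property
    def is_perfect(self) -> bool:
        return self.mismatches == 0 and self.gap_bases == 0


@dataclass(frozen=True)
class AmpliconHit:
    """One simulated amplification: a convergent pair of binding sites.

    ``left_site`` lies on the plus strand, ``right_site`` on the minus
    strand; the amplicon spans end-to-end from the left site's start to the
    right site's end, primer footprints included.
    """

    event_id: str
    sequence_index: int
    method_id: str
    pair_kind: str  # one of PAIR_KINDS
    left_site: BindingSite
    right_site: BindingSite
    start: int
    end: int

    @property
    def amplicon_length(self) -> int:
        return self.end - self.start

    @property
    def total_edits(self) -> int:
        return self.left_site.edits + self.right_site.edits

    @property
    def is_self_pair(self) -> bool:
        return self.pair_kind != "p1_p2"

    @property
    def primers_perfect(self) -> bool:
        return self.left_site.is_perfect and self.right_site.is_perfect


@dataclass(frozen=True)
class ProbeAlignment:
    """Best probe-vs-amplicon alignment over the two orientations.

    ``classification`` is ``perfect`` for exact full-length hybridisation,
    ``imperfect`` within the mismatch/gap budgets, ``none`` otherwise.
    """

    strand: str  # amplicon orientation that won: "plus" | "minus"
    mismatches: Optional[int]
    gap_bases: Optional[int]
    covered: bool
    classification: str  # "perfect" | "imperfect" | "none"


@dataclass(frozen=True)
class PCRParams:
    """Simulation thresholds: per-primer edit budgets and amplicon bounds."""

    max_mismatches: int = 2
    max_gaps: int = 2
    amplicon_min: int = 20
    amplicon_max: int = 500

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.max_gaps < 0:
            raise ValueError("edit budgets must be non-negative")
        if self.amplicon_min <= 0 or self.amplicon_min >= self.amplicon_max:
            raise ValueError("require 0 < amplicon_min < amplicon_max")

    def as_dict(self) -> dict[str, int]:
        return {
            "max_mismatches": self.max_mismatches,
            "max_gaps": self.max_gaps,
            "amplicon_min": self.amplicon_min,
            "amplicon_max": self.amplicon_max,
        }


@dataclass(frozen=True)
class PairScore:
    """Pre-computed detection score for one method x event pair.

    2 = perfect annealing of both primers and (if present) probe;
    1 = amplicon predicted but with imperfect primer/probe binding;
    0 = no amplicon within the thresholds.  ``self_pair_warning`` flags
    pairs whose retained hits include a same-primer amplicon.
    """

    event_id: str
    method_id: str
    score: int
    self_pair_warning: bool = False
    best_hit: Optional[AmpliconHit] = None
    probe_alignment: Optional[ProbeAlignment] = None

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2):
            raise ValueError(f"score must be 0, 1 or 2, got {self.score}")

    def cell_text(self) -> str:
        """Matrix cell rendering: the score, '!'-suffixed on a warning."""
        return f"{self.score}!" if self.self_pair_warning else str(self.score)


@dataclass
class MatrixView:
    """An events x methods grid of scores, in requested order."""

    events: list[str]
    methods: list[str]
    cells: list[list[PairScore]]

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.events) or any(
            len(row) != len(self.methods) for row in self.cells
        ):
            raise ValueError("matrix grid dimensions do not match axes")

    def cell(self, event_id: str, method_id: str) -> PairScore:
        i = self.events.index(event_id)
        j = self.methods.index(method_id)
        return self.cells[i][j]


@dataclass(frozen=True)
class ScreeningPattern:
    """Observed screening outcome: method_id -> 'positive' | 'negative'."""

    assignments: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen = set()
        for method_id, call in self.assignments:
            if call not in ("positive", "negative"):
                raise ValueError(f"call for {method_id} must be positive/negative, got {call!r}")
            if method_id in seen:
                raise ValueError(f"method {method_id} appears twice in pattern")
            seen.add(method_id)

    @classmethod
    def from_dict(cls, mapping: dict[str, str]) -> "ScreeningPattern":
        return cls(tuple(mapping.items()))

    @property
    def positives(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.assignments if c == "positive")

    @property
    def negatives(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.assignments if c == "negative")

    @property
    def method_ids(self) -> tuple[str, ...]:
        return tuple(m for m, _ in self.assignments)


@dataclass
class FinderResult:
    """Minimal event combinations explaining a screening pattern."""

    combinations: list[frozenset[str]]
    matrix_excerpt: MatrixView = field(default=None)  # type: ignore[assignment]

    @property
    def involved_events(self) -> list[str]:
        return sorted(set().union(*self.combinations)) if self.combinations else []
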