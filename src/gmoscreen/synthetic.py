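"""Deterministic synthetic panels standing in for confidential data.

Real GM event sequences are Confidential Business Information and cannot
be distributed, so every stage of this package is exercised on synthetic
panels: random backbones into which primer/probe cassettes are planted so
that each event x method cell realises a chosen 0/1/2 score.

* score-2 cells get an exact ``primer1 + spacer (+ exact probe copy) +
  rc(primer2)`` cassette;
* score-1 cells get the same cassette with exactly one substitution in a
  primer footprint (or, optionally, in the probe copy);
* score-0 cells get no cassette;
* designated self-pair cells additionally get a ``primer1 + spacer +
  rc(primer1)`` cassette (probe copy included for probe-bearing methods,
  and degraded to match the planted score — a retained self-pair hit
  always contributes to the score, so a self-pair cell must be planted
  with score >= 1).

Each generated event is verified by re-scoring every cell with the
production scorer; on any disagreement (e.g. a chance binding site in the
random backbone) the event is resampled with a fresh deterministic
sub-seed.  Output files are byte-identical across runs for a fixed spec.

Spacer lengths default to 30-160 bases so that amplicons sit in the
50-200 bp band typical of validated TaqMan assays.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import write_events_fasta, write_methods_table
from .models import (
    DetectionMethod,
    GMOEvent,
    MatrixView,
    PairScore,
    PCRParams,
)
from .nucleotides import reverse_complement
from .scoring import export_matrix_csv, score_pair

__all__ = [
    "PanelSpecError",
    "PanelSpec",
    "Panel",
    "make_panel_spec",
    "generate_panel",
    "write_panel",
    "mutate_site",
]

_BASES = np.array(list("ACGT"))


class PanelSpecError(Exception):
    """The requested panel cannot be realised."""


@dataclass(frozen=True)
class PanelSpec:
    """Full description of a synthetic panel; generation is a pure
    function of this object."""

    n_events: int
    n_methods: int
    planted_score_grid: tuple[tuple[int, ...], ...]
    backbone_length: int = 2000
    primer_length: int = 20
    probe_length: int = 24
    spacer_range: tuple[int, int] = (30, 160)
    self_pair_cells: frozenset[tuple[int, int]] = frozenset()
    two_sequence_events: frozenset[int] = frozenset()
    probed_methods: Optional[frozenset[int]] = None  # default: even indices
    score1_in_probe: bool = False
    seed: int = 0
    params: PCRParams = field(default_factory=PCRParams)

    def __post_init__(self) -> None:
        grid = self.planted_score_grid
        if len(grid) != self.n_events or any(len(r) != self.n_methods for r in grid):
            raise PanelSpecError("planted_score_grid dimensions do not match panel shape")
        if any(v not in (0, 1, 2) for r in grid for v in r):
            raise PanelSpecError("planted scores must be 0, 1 or 2")
        lo, hi = self.spacer_range
        if lo < 0 or lo > hi:
            raise PanelSpecError("invalid spacer_range")
        amp_min = 2 * self.primer_length + lo
        amp_max = 2 * self.primer_length + hi
        if amp_min < self.params.amplicon_min or amp_max > self.params.amplicon_max:
            raise PanelSpecError(
                f"spacer_range {self.spacer_range} yields amplicons "
                f"[{amp_min}, {amp_max}] outside "
                f"[{self.params.amplicon_min}, {self.params.amplicon_max}]"
            )
        if hi < self.probe_length:
            raise PanelSpecError("spacer_range cannot accommodate the probe")
        for (i, j) in self.self_pair_cells:
            if not (0 <= i < self.n_events and 0 <= j < self.n_methods):
                raise PanelSpecError(f"self-pair cell {(i, j)} outside the grid")
            if grid[i][j] == 0:
                raise PanelSpecError(
                    f"self-pair cell {(i, j)} has planted score 0; a retained "
                    "self-pair amplicon forces a score >= 1"
                )

    @property
    def probed(self) -> frozenset[int]:
        if self.probed_methods is not None:
            return self.probed_methods
        return frozenset(j for j in range(self.n_methods) if j % 2 == 0)


@dataclass
class Panel:
    """A realised synthetic panel plus its planted ground truth."""

    spec: PanelSpec
    events: list[GMOEvent]
    methods: list[DetectionMethod]

    @property
    def grid(self) -> tuple[tuple[int, ...], ...]:
        return self.spec.planted_score_grid

    def truth_matrix(self) -> MatrixView:
        cells = [
            [
                PairScore(
                    e.event_id,
                    m.method_id,
                    self.grid[i][j],
                    (i, j) in self.spec.self_pair_cells,
                )
                for j, m in enumerate(self.methods)
            ]
            for i, e in enumerate(self.events)
        ]
        return MatrixView(
            events=[e.event_id for e in self.events],
            methods=[m.method_id for m in self.methods],
            cells=cells,
        )


def make_panel_spec(
    n_events: int,
    n_methods: int,
    seed: int = 0,
    n_self_pairs: int = 0,
    score_weights: tuple[float, float, float] = (0.5, 0.1, 0.4),
    **kwargs,
) -> PanelSpec:
    """Draw a random planted grid and self-pair cells from *seed*.

    Score 1 is drawn rarely by default, matching its rarity in validated
    screening assays against real event sequences.
    """
    rng = np.random.default_rng([seed, 101])
    grid = tuple(
        tuple(int(v) for v in rng.choice(3, size=n_methods, p=score_weights))
        for _ in range(n_events)
    )
    nonzero = [(i, j) for i in range(n_events) for j in range(n_methods) if grid[i][j]]
    if n_self_pairs > len(nonzero):
        raise PanelSpecError("not enough non-zero cells for the requested self pairs")
    chosen = rng.choice(len(nonzero), size=n_self_pairs, replace=False)
    cells = frozenset(nonzero[int(k)] for k in chosen)
    return PanelSpec(
        n_events=n_events,
        n_methods=n_methods,
        planted_score_grid=grid,
        self_pair_cells=cells,
        seed=seed,
        **kwargs,
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _substitute(rng: np.random.Generator, seq: str, pos: int) -> str:
    others = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + others[int(rng.integers(0, 3))] + seq[pos + 1 :]


def mutate_site(
    sequence: str, interval: tuple[int, int], n_substitutions: int, seed: int
) -> str:
    """Substitute exactly *n* distinct positions inside *interval* to a
    different base; deterministic given *seed*."""
    start, end = interval
    if not (0 <= start <= end <= len(sequence)):
        raise ValueError(f"interval {interval} outside sequence of length {len(sequence)}")
    if n_substitutions > end - start:
        raise ValueError("more substitutions than interval positions")
    rng = np.random.default_rng(seed)
    positions = rng.choice(np.arange(start, end), size=n_substitutions, replace=False)
    out = sequence
    for pos in sorted(int(p) for p in positions):
        out = _substitute(rng, out, pos)
    return out


def _build_cassette(
    rng: np.random.Generator,
    spec: PanelSpec,
    method: DetectionMethod,
    score: int,
    self_pair: bool,
) -> str:
    """One planted cassette realising *score* for *method*."""
    lo, hi = spec.spacer_range
    if method.has_probe:
        lo = max(lo, spec.probe_length)
    spacer_len = int(rng.integers(lo, hi + 1))
    if method.has_probe:
        probe_copy = method.probe
        left_pad = int(rng.integers(0, spacer_len - len(probe_copy) + 1))
        if score == 1 and spec.score1_in_probe and not self_pair:
            probe_copy = _substitute(
                rng, probe_copy, int(rng.integers(0, len(probe_copy)))
            )
        inner = (
            _random_seq(rng, left_pad)
            + probe_copy
            + _random_seq(rng, spacer_len - left_pad - len(probe_copy))
        )
    else:
        inner = _random_seq(rng, spacer_len)

    left = method.primer1
    right = reverse_complement(method.primer1 if self_pair else method.primer2)
    degrade_primer = score == 1 and not (
        spec.score1_in_probe and method.has_probe and not self_pair
    )
    if degrade_primer:
        left = _substitute(rng, left, int(rng.integers(0, len(left))))
    return left + inner + right


def _build_event(
    spec: PanelSpec,
    methods: list[DetectionMethod],
    event_index: int,
    attempt: int,
) -> GMOEvent:
    rng = np.random.default_rng([spec.seed, 211, event_index, attempt])
    grid_row = spec.planted_score_grid[event_index]

    cassettes: list[str] = []
    for j, m in enumerate(methods):
        if grid_row[j] > 0:
            cassettes.append(_build_cassette(rng, spec, m, grid_row[j], self_pair=False))
    for j, m in enumerate(methods):
        if (event_index, j) in spec.self_pair_cells:
            cassettes.append(_build_cassette(rng, spec, m, grid_row[j], self_pair=True))

    n_seqs = 2 if event_index in spec.two_sequence_events else 1
    per_seq: list[list[str]] = [[] for _ in range(n_seqs)]
    for k, cassette in enumerate(cassettes):
        per_seq[k % n_seqs].append(cassette)

    sequences = []
    for chunk in per_seq:
        total = sum(len(c) for c in chunk)
        free = spec.backbone_length - total
        if free < 0:
            raise PanelSpecError(
                f"backbone_length {spec.backbone_length} too short for "
                f"{len(chunk)} cassettes totalling {total} bases"
            )
        backbone = _random_seq(rng, spec.backbone_length)
        cuts = sorted(int(c) for c in rng.integers(0, free + 1, size=len(chunk)))
        consumed = 0
        for cut, cassette in zip(cuts, chunk):
            pos = cut + consumed
            backbone = backbone[:pos] + cassette + backbone[pos + len(cassette) :]
            consumed += len(cassette)
        sequences.append(backbone)

    event_id = f"SYN-EV{event_index + 1:03d}"
    return GMOEvent(event_id=event_id, sequences=tuple(sequences))


def generate_panel(spec: PanelSpec, max_attempts: int = 30) -> Panel:
    """Realise a panel; every cell verified against the planted grid.

    Events whose random backbone produces any scoring disagreement (a
    chance binding site, a spurious self-pair) are rejection-sampled with
    fresh deterministic sub-seeds.
    """
    rng_m = np.random.default_rng([spec.seed, 131])
    methods: list[DetectionMethod] = []
    types = ("element_specific", "construct_specific")
    for j in range(spec.n_methods):
        methods.append(
            DetectionMethod(
                method_id=f"QT-SYN-00-{j + 1:03d}",
                method_type=types[j % 2],
                target_name=f"elem{j + 1}",
                primer1=_random_seq(rng_m, spec.primer_length),
                primer2=_random_seq(rng_m, spec.primer_length),
                probe=_random_seq(rng_m, spec.probe_length) if j in spec.probed else None,
            )
        )

    events: list[GMOEvent] = []
    for i in range(spec.n_events):
        for attempt in range(max_attempts):
            event = _build_event(spec, methods, i, attempt)
            ok = True
            for j, m in enumerate(methods):
                ps = score_pair(m, event, spec.params)
                if ps.score != spec.planted_score_grid[i][j] or (
                    ps.self_pair_warning != ((i, j) in spec.self_pair_cells)
                ):
                    ok = False
                    break
            if ok:
                events.append(event)
                break
        else:
            raise RuntimeError(
                f"could not realise event {i} in {max_attempts} attempts"
            )
    return Panel(spec=spec, events=events, methods=methods)


def write_panel(panel: Panel, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write events FASTA, methods table and ground-truth matrix CSV."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "events": os.path.join(out_dir, "events.fasta"),
        "methods": os.path.join(out_dir, "methods.tsv"),
        "truth": os.path.join(out_dir, "truth.csv"),
    }
    write_events_fasta(panel.events, paths["events"])
    write_methods_table(panel.methods, paths["methods"])
    export_matrix_csv(panel.truth_matrix(), paths["truth"])
    return paths
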