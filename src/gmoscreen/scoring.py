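"""0/1/2 scoring of method x event pairs, score store and matrix views.

For each pair, amplicon hits are pooled over every template sequence of
the event and all three primer pairings.  If the method carries a probe,
each hit's amplicon is probe-classified and hits whose probe cannot bind
within the budgets are discarded.  The pair's score is the best retained
hit: 2 when both primer footprints are exact and the probe (if any) is
perfect, 1 for any imperfect retained hit, 0 when nothing remains.
Retained same-primer amplicons set a warning flag — they count, but fall
outside the assay's intent and are highlighted in the matrices.

The pre-computed scores live in a single-file tabular store (TSV with a
header recording the simulation thresholds), unique per
(event_id, method_id) with upsert semantics.
"""

from __future__ import annotations

import csv
import io as _io
import os
from typing import Iterable, Optional

from .models import (
    AmpliconHit,
    DetectionMethod,
    GMOEvent,
    MatrixView,
    PairScore,
    PCRParams,
    ProbeAlignment,
)
from .pcr import enumerate_amplicons
from .probes import align_probe

__all__ = [
    "StoreError",
    "score_pair",
    "ScoreStore",
    "persist_scores",
    "load_scores",
    "build_matrix",
    "export_matrix_csv",
    "parse_matrix_csv",
    "matrix_to_html",
]


class StoreError(Exception):
    """Raised on missing pairs, corrupt files or threshold mismatches."""


def _hit_quality(
    method: DetectionMethod,
    hit: AmpliconHit,
    probe_aln: Optional[ProbeAlignment],
) -> int:
    if hit.primers_perfect and (
        not method.has_probe or probe_aln.classification == "perfect"
    ):
        return 2
    return 1


def score_pair(
    method: DetectionMethod,
    event: GMOEvent,
    params: PCRParams = PCRParams(),
) -> PairScore:
    """Simulate the full detection of *event* by *method* and score it."""
    retained: list[tuple[int, AmpliconHit, Optional[ProbeAlignment]]] = []
    for idx, seq in enumerate(event.sequences):
        for hit in enumerate_amplicons(method, seq, event.event_id, idx, params):
            probe_aln = None
            if method.has_probe:
                probe_aln = align_probe(
                    method.probe,
                    seq[hit.start : hit.end],
                    params.max_mismatches,
                    params.max_gaps,
                )
                if probe_aln.classification == "none":
                    continue
            retained.append((_hit_quality(method, hit, probe_aln), hit, probe_aln))

    if not retained:
        return PairScore(event.event_id, method.method_id, 0)

    quality, best, best_probe = min(
        retained,
        key=lambda t: (-t[0], t[1].total_edits, t[1].sequence_index, t[1].start),
    )
    return PairScore(
        event_id=event.event_id,
        method_id=method.method_id,
        score=max(q for q, _, _ in retained),
        self_pair_warning=any(h.is_self_pair for _, h, _ in retained),
        best_hit=best,
        probe_alignment=best_probe,
    )


_STORE_MAGIC = "#gmoscreen-score-store\tv1"
_STORE_HEADER = ["event_id", "method_id", "score", "warning"]


class ScoreStore:
    """In-memory pair-score table with a deterministic single-file format.

    Rows are unique on (event_id, method_id); :meth:`put` upserts.  The
    file header records the simulation thresholds so that scores computed
    under different thresholds cannot be mixed silently.
    """

    def __init__(self, params: Optional[PCRParams] = None):
        self.params = params or PCRParams()
        self._pairs: dict[tuple[str, str], tuple[int, bool]] = {}

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._pairs

    def put(self, pair: PairScore) -> None:
        self._pairs[(pair.event_id, pair.method_id)] = (
            pair.score,
            pair.self_pair_warning,
        )

    def get(self, event_id: str, method_id: str) -> PairScore:
        try:
            score, warning = self._pairs[(event_id, method_id)]
        except KeyError:
            raise StoreError(
                f"no score stored for event {event_id!r} x method {method_id!r}"
            ) from None
        return PairScore(event_id, method_id, score, warning)

    def event_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e, _ in self._pairs:
            seen.setdefault(e)
        return list(seen)

    def method_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, m in self._pairs:
            seen.setdefault(m)
        return list(seen)

    def save(self, path: str | os.PathLike) -> None:
        """Write atomically (temp file + rename); rows sorted for
        deterministic bytes."""
        p = self.params
        lines = [_STORE_MAGIC]
        lines.append(
            "#params\tmax_mismatches={}\tmax_gaps={}\tamplicon_min={}\tamplicon_max={}".format(
                p.max_mismatches, p.max_gaps, p.amplicon_min, p.amplicon_max
            )
        )
        lines.append("\t".join(_STORE_HEADER))
        for (e, m), (score, warning) in sorted(self._pairs.items()):
            lines.append(f"{e}\t{m}\t{score}\t{int(warning)}")
        tmp = f"{os.fspath(path)}.tmp"
        with open(tmp, "w", encoding="utf-8", newline="") as fh:
            fh.write("\n".join(lines) + "\n")
        os.replace(tmp, path)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "ScoreStore":
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        if not lines or lines[0] != _STORE_MAGIC:
            raise StoreError(f"{path}: not a score-store file")
        try:
            kv = dict(
                item.split("=", 1) for item in lines[1].split("\t")[1:]
            )
            params = PCRParams(**{k: int(v) for k, v in kv.items()})
        except Exception as exc:
            raise StoreError(f"{path}: corrupt parameter header") from exc
        if len(lines) < 3 or lines[2] != "\t".join(_STORE_HEADER):
            raise StoreError(f"{path}: missing column header")
        store = cls(params)
        for n, line in enumerate(lines[3:], start=4):
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise StoreError(f"{path}:{n}: expected 4 tab-separated fields")
            e, m, score, warning = fields
            try:
                store._pairs[(e, m)] = (int(score), bool(int(warning)))
            except ValueError as exc:
                raise StoreError(f"{path}:{n}: corrupt row") from exc
        return store

    def check_params(self, params: PCRParams) -> None:
        if params != self.params:
            raise StoreError(
                "score store was built with thresholds "
                f"{self.params.as_dict()} but {params.as_dict()} requested; "
                "rebuild the store"
            )


def persist_scores(
    pairs: Iterable[PairScore],
    path: str | os.PathLike,
    params: Optional[PCRParams] = None,
) -> ScoreStore:
    store = ScoreStore(params)
    for p in pairs:
        store.put(p)
    store.save(path)
    return store


def load_scores(path: str | os.PathLike) -> ScoreStore:
    return ScoreStore.load(path)


def build_matrix(
    events: Iterable, methods: Iterable, store: ScoreStore
) -> MatrixView:
    """Assemble the events x methods grid from the store, request order
    preserved.  Missing pairs raise :class:`StoreError` naming the pair."""
    event_ids = [getattr(e, "event_id", e) for e in events]
    method_ids = [getattr(m, "method_id", m) for m in methods]
    cells = [
        [store.get(e, m) for m in method_ids]
        for e in event_ids
    ]
    return MatrixView(events=event_ids, methods=method_ids, cells=cells)


def export_matrix_csv(matrix: MatrixView, path: str | os.PathLike) -> None:
    """CSV export: first column event_id, one column per method; cells are
    the score with a ``!`` suffix on a self-pair warning."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["event_id", *matrix.methods])
        for event_id, row in zip(matrix.events, matrix.cells):
            writer.writerow([event_id, *(cell.cell_text() for cell in row)])


def parse_matrix_csv(path: str | os.PathLike) -> MatrixView:
    """Read back a matrix CSV (scores and warning flags only)."""
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:1] != ["event_id"]:
        raise ValueError(f"{path}: not a matrix CSV")
    methods = rows[0][1:]
    events = []
    cells = []
    for row in rows[1:]:
        if not row:
            continue
        event_id, *vals = row
        if len(vals) != len(methods):
            raise ValueError(f"{path}: row {event_id!r} has {len(vals)} cells")
        events.append(event_id)
        parsed = []
        for m, v in zip(methods, vals):
            warning = v.endswith("!")
            parsed.append(PairScore(event_id, m, int(v.rstrip("!")), warning))
        cells.append(parsed)
    return MatrixView(events=events, methods=methods, cells=cells)


def matrix_to_html(matrix: MatrixView, title: str = "Screening matrix") -> str:
    """Static HTML rendering of the grid (presentation only)."""
    out = _io.StringIO()
    out.write(f"<!DOCTYPE html>\n<html><head><title>{title}</title></head><body>\n")
    out.write(f"<h1>{title}</h1>\n<table border='1'>\n<tr><th>event_id</th>")
    for m in matrix.methods:
        out.write(f"<th>{m}</th>")
    out.write("</tr>\n")
    for event_id, row in zip(matrix.events, matrix.cells):
        out.write(f"<tr><td>{event_id}</td>")
        for cell in row:
            out.write(f"<td>{cell.cell_text()}</td>")
        out.write("</tr>\n")
    out.write("</table>\n</body></html>\n")
    return out.getvalue()
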