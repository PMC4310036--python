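"""Readers and writers for method tables, event FASTA files and patterns.

Event FASTA headers follow the ``>eventID|label`` convention; multiple
records sharing an event identifier (retransformations, stacked events)
are grouped into one :class:`~gmoscreen.models.GMOEvent` in file order.
The methods table is a delimited file (tab or comma, auto-detected from
the header) with columns method_id, method_type, target_name, primer1,
primer2, probe — the probe field may be empty.
"""

from __future__ import annotations

import csv
import os

from Bio import SeqIO

from .models import DetectionMethod, GMOEvent, ScreeningPattern

__all__ = [
    "FormatError",
    "read_methods_table",
    "write_methods_table",
    "read_events_fasta",
    "write_events_fasta",
    "read_pattern_file",
]

METHOD_COLUMNS = ["method_id", "method_type", "target_name", "primer1", "primer2", "probe"]


class FormatError(Exception):
    """Malformed input file."""


def read_methods_table(path: str | os.PathLike) -> list[DetectionMethod]:
    """Parse a methods table; order preserved, duplicate ids rejected."""
    with open(path, encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty methods table")
        delimiter = "\t" if "\t" in header_line else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = [c for c in METHOD_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
        methods: list[DetectionMethod] = []
        seen: set[str] = set()
        for n, row in enumerate(reader, start=2):
            mid = (row["method_id"] or "").strip()
            if mid in seen:
                raise FormatError(f"{path}: duplicate method_id {mid!r}")
            seen.add(mid)
            try:
                methods.append(
                    DetectionMethod(
                        method_id=mid,
                        method_type=(row["method_type"] or "").strip(),
                        target_name=(row["target_name"] or "").strip(),
                        primer1=(row["primer1"] or "").strip(),
                        primer2=(row["primer2"] or "").strip(),
                        probe=(row["probe"] or "").strip(),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {n}: {exc}") from exc
    return methods


def write_methods_table(
    methods: list[DetectionMethod],
    path: str | os.PathLike,
    delimiter: str = "\t",
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(METHOD_COLUMNS)
        for m in methods:
            writer.writerow(
                [m.method_id, m.method_type, m.target_name, m.primer1, m.primer2, m.probe or ""]
            )


def read_events_fasta(path: str | os.PathLike) -> list[GMOEvent]:
    """Parse event sequences, grouping records by the eventID header token."""
    grouped: dict[str, tuple[list[str], list[str]]] = {}
    for record in SeqIO.parse(os.fspath(path), "fasta"):
        header = record.description
        event_id, _, label = header.partition("|")
        event_id = event_id.strip()
        if not event_id:
            raise FormatError(f"{path}: malformed header {header!r}: no eventID token")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {header!r}")
        seqs, labels = grouped.setdefault(event_id, ([], []))
        seqs.append(seq)
        labels.append(label.strip())
    if not grouped:
        raise FormatError(f"{path}: no FASTA records")
    events = []
    for event_id, (seqs, labels) in grouped.items():
        try:
            events.append(
                GMOEvent(event_id=event_id, sequences=tuple(seqs), sequence_labels=tuple(labels))
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return events


def write_events_fasta(
    events: list[GMOEvent],
    path: str | os.PathLike,
    line_width: int = 70,
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for event in events:
            for label, seq in zip(event.sequence_labels, event.sequences):
                fh.write(f">{event.event_id}|{label}\n")
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def read_pattern_file(path: str | os.PathLike) -> ScreeningPattern:
    """Two-column delimited pattern file: method_id, then +/- (or the
    words positive/negative)."""
    calls: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split("\t")
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                raise FormatError(f"{path}:{n}: expected 'method_id<TAB>+/-'")
            mid, call = parts
            norm = {"+": "positive", "-": "negative",
                    "positive": "positive", "negative": "negative"}.get(call)
            if norm is None:
                raise FormatError(f"{path}:{n}: unrecognised call {call!r}")
            calls.append((mid, norm))
    try:
        return ScreeningPattern(tuple(calls))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
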