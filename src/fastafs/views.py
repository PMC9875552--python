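"""Read-only metadata views: labels.txt, infos.csv and infos.txt.

All three render from whatever index they are given — the on-disk
:class:`~fastafs.model.FastaIndex` or the edit-aware effective index — so
they reflect staged edits in real time.  The rendered views only rely on the
attributes shared by both entry types: ``header``, ``length_bases``,
``seq_start`` and ``seq_end``.

labels.txt lines omit the leading ``>`` so the file doubles as a plain
ID/description table.  infos.csv columns (id, description, length and byte
offsets) are the minimal set that supports downstream scripting; see the
README for how to extend them.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

CSV_COLUMNS = ("id", "description", "length", "start_offset", "end_offset")


@dataclass(frozen=True)
class SequenceInfoRow:
    id: str
    description: str
    length: int
    start_offset: int
    end_offset: int


def sequence_rows(index) -> list[SequenceInfoRow]:
    """One row per record, in file order."""
    return [
        SequenceInfoRow(
            id=e.header.id,
            description=e.header.description or "",
            length=e.length_bases,
            start_offset=e.seq_start,
            end_offset=e.seq_end,
        )
        for e in index
    ]


def render_labels(index) -> str:
    """The header register: one raw header per line, ``>`` stripped."""
    return "".join(e.header.label + "\n" for e in index)


def render_infos_csv(index) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for row in sequence_rows(index):
        writer.writerow([row.id, row.description, row.length,
                         row.start_offset, row.end_offset])
    return buf.getvalue()


def render_infos_txt(index, source_path: str = "", source_size: int | None = None) -> str:
    """Human-readable summary plus an aligned per-sequence table."""
    rows = sequence_rows(index)
    lines = []
    if source_path:
        lines.append(f"source: {source_path}")
    if source_size is not None:
        lines.append(f"file size: {source_size} bytes")
    lines.append(f"{len(rows)} sequences")
    if rows:
        lengths = [r.length for r in rows]
        lines.append(f"total bases: {sum(lengths)}")
        lines.append(f"shortest: {min(lengths)} bases; longest: {max(lengths)} bases")
        lines.append("")
        header = ("id", "length", "start", "end", "description")
        table = [header] + [
            (r.id, str(r.length), str(r.start_offset), str(r.end_offset),
             r.description)
            for r in rows
        ]
        widths = [max(len(row[c]) for row in table) for c in range(len(header) - 1)]
        for row in table:
            cells = [row[c].ljust(widths[c]) for c in range(len(widths))]
            lines.append(("  ".join(cells + [row[-1]])).rstrip())
    return "\n".join(lines) + "\n"
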