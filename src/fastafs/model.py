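"""multiFASTA parsing and byte-exact indexing.

A mounted file is described by a :class:`FastaIndex`: one
:class:`RecordIndexEntry` per record, carrying the byte coordinates of the
header and sequence body plus a run-length-compressed line layout
(:class:`LineLayout`).  The index is faidx-like but stricter: it records
*every* line length (including zero-length blank lines), so the original file
can be reconstructed byte-for-byte from the index and the raw bytes, whatever
the wrapping, gapping or padding of the input.

Coordinates are byte offsets into the mounted file.  ``seq_start`` points at
the first body byte (just past the header's newline) and ``seq_end`` one past
the last body byte, *including* the body's internal and terminal newlines and
any blank lines preceding the next header — so concatenating
``[header_start, seq_end)`` spans in order reproduces the file exactly
(after the optional blank-line preamble).

Only UNIX line delimiters are accepted; a single ``\\r`` anywhere rejects the
input.  Sequence bytes themselves are unconstrained (IUPAC, gaps, arbitrary
printable characters).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator

from .errors import (
    DuplicateId,
    InvalidHeader,
    InvalidId,
    InvalidRegion,
    NonUnixLineEndings,
    NotFasta,
    NotFound,
    OutOfRange,
)

#: Longest accepted sequence ID, in bytes (common filesystem name limit).
MAX_ID_BYTES = 255

_ID_FORBIDDEN = (b"/", b"\x00")
_WHITESPACE = b" \t\x0b\x0c"


def _decode(raw: bytes) -> str:
    # surrogateescape keeps arbitrary header bytes round-trippable through str
    return raw.decode("utf-8", "surrogateescape")


def _encode(text: str) -> bytes:
    return text.encode("utf-8", "surrogateescape")


@dataclass(frozen=True)
class FastaHeader:
    """A record header: ID, optional description, and the verbatim line.

    ``raw`` is the original header line without the leading ``>`` and without
    the newline; re-emitting ``b">" + raw + b"\\n"`` reproduces the header
    byte-for-byte, whatever whitespace separated ID and description.
    """

    id: str
    description: str | None
    raw: bytes

    @property
    def id_bytes(self) -> bytes:
        return _encode(self.id)

    @property
    def label(self) -> str:
        """The header as shown in labels.txt (no leading ``>``)."""
        return _decode(self.raw)


def validate_id_bytes(idb: bytes) -> None:
    """Check that ``idb`` is usable as a filename component.

    Raises InvalidHeader when empty, InvalidId otherwise.
    """
    if not idb:
        raise InvalidHeader("sequence has no ID")
    if len(idb) > MAX_ID_BYTES:
        raise InvalidId(f"id longer than {MAX_ID_BYTES} bytes")
    if idb in (b".", b".."):
        raise InvalidId(f"id {idb!r} is a reserved filename")
    for bad in _ID_FORBIDDEN:
        if bad in idb:
            raise InvalidId(f"id {idb!r} contains forbidden byte {bad!r}")
    if any(idb.find(ws) != -1 for ws in (b" ", b"\t", b"\n", b"\x0b", b"\x0c")):
        raise InvalidId(f"id {idb!r} contains whitespace")


def parse_header_line(line: bytes) -> FastaHeader:
    """Parse one ``>`` header line (no trailing newline) into a FastaHeader.

    The ID is the maximal run of non-whitespace bytes after ``>``; the
    description is whatever follows the first whitespace run (an empty
    description is preserved as "present but empty").
    """
    if not line.startswith(b">"):
        raise InvalidHeader(f"header line must start with '>': {line[:30]!r}")
    if b"\n" in line:
        raise InvalidHeader("header line contains a newline")
    body = line[1:]
    m = re.match(rb"[^ \t\x0b\x0c]*", body)
    idb = m.group(0) if m else b""
    validate_id_bytes(idb)
    rest = body[len(idb):]
    description = _decode(rest.lstrip(_WHITESPACE)) if rest else None
    return FastaHeader(id=_decode(idb), description=description, raw=body)


class LineLayout:
    """Run-length-compressed per-line base counts of one record body.

    Stored as ``(count, width)`` runs so a uniformly wrapped chromosome costs
    O(1) memory.  Zero-width runs are blank lines (one newline byte, no
    bases); they participate in byte arithmetic but contribute no bases.
    """

    __slots__ = ("runs", "total_bases", "n_lines")

    def __init__(self, runs: list[tuple[int, int]]):
        self.runs = runs
        self.total_bases = sum(c * w for c, w in runs)
        self.n_lines = sum(c for c, _ in runs)

    @classmethod
    def from_lengths(cls, lengths: Iterable[int]) -> "LineLayout":
        runs: list[tuple[int, int]] = []
        for length in lengths:
            if runs and runs[-1][1] == length:
                runs[-1] = (runs[-1][0] + 1, length)
            else:
                runs.append((1, length))
        return cls(runs)

    def lengths(self) -> list[int]:
        """Expanded per-line base counts (small records / tests only)."""
        out: list[int] = []
        for count, width in self.runs:
            out.extend([width] * count)
        return out

    def base_offset(self, base_index: int) -> int:
        """Byte offset within the body of the 0-based ``base_index``-th base,
        accounting for one newline byte after every line."""
        if base_index < 0:
            raise OutOfRange(f"negative base index {base_index}")
        offset = 0
        remaining = base_index
        for count, width in self.runs:
            if width == 0:
                offset += count  # blank lines: newline byte only
                continue
            run_bases = count * width
            if remaining < run_bases:
                line_i, col = divmod(remaining, width)
                return offset + line_i * (width + 1) + col
            remaining -= run_bases
            offset += count * (width + 1)
        raise OutOfRange(f"base index {base_index} beyond {self.total_bases} bases")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LineLayout) and self.runs == other.runs

    def __repr__(self) -> str:
        return f"LineLayout({self.runs!r})"


@dataclass(frozen=True)
class RecordIndexEntry:
    """Byte coordinates and line layout of one record in the mounted file."""

    header: FastaHeader
    header_start: int
    seq_start: int
    seq_end: int
    length_bases: int
    layout: LineLayout

    @property
    def line_lengths(self) -> list[int]:
        return self.layout.lengths()

    @property
    def body_nbytes(self) -> int:
        return self.seq_end - self.seq_start


class FastaIndex:
    """Ordered, unique-ID map of records plus file-level metadata."""

    def __init__(self, records: list[RecordIndexEntry], source_size: int,
                 preamble: bytes = b""):
        self._records = records
        self._by_id = {r.header.id: r for r in records}
        if len(self._by_id) != len(records):  # defensive; scan already checks
            raise DuplicateId("duplicate ids in index")
        self.source_size = source_size
        self.preamble = preamble

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[RecordIndexEntry]:
        return iter(self._records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __getitem__(self, seq_id: str) -> RecordIndexEntry:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise NotFound(f"no sequence named {seq_id!r}") from None

    def get(self, seq_id: str) -> RecordIndexEntry | None:
        return self._by_id.get(seq_id)

    def ids(self) -> list[str]:
        return [r.header.id for r in self._records]

    @property
    def records(self) -> list[RecordIndexEntry]:
        return list(self._records)


def _as_bytes_like(source) -> bytes:
    """Accept bytes/bytearray/mmap or a readable binary stream."""
    if isinstance(source, (bytes, bytearray, memoryview)):
        return bytes(source) if isinstance(source, memoryview) else source
    if hasattr(source, "find") and hasattr(source, "__getitem__"):
        return source  # mmap quacks enough
    if hasattr(source, "read"):
        return source.read()
    raise TypeError(f"cannot scan source of type {type(source)!r}")


def scan_multifasta(source) -> FastaIndex:
    """Index a multiFASTA in one sequential pass.

    Accepts bytes, a bytes-like object (mmap) or a binary stream.  Blank lines
    inside a record are recorded as zero-length line entries; blank lines
    before a ``>`` are attributed to the preceding record (or to the file
    preamble if no record has started), so reconstruction from spans is
    byte-exact.
    """
    data = _as_bytes_like(source)
    n = len(data)
    if n and data.find(b"\r") != -1:
        raise NonUnixLineEndings("input contains '\\r'; lines must use UNIX delimiters")

    records: list[RecordIndexEntry] = []
    seen: set[str] = set()
    preamble_end = 0
    # current record accumulator: header, header_start, seq_start, lengths
    cur_header: FastaHeader | None = None
    cur_hstart = 0
    cur_sstart = 0
    cur_lengths: list[int] = []

    def close(seq_end: int) -> None:
        layout = LineLayout.from_lengths(cur_lengths)
        records.append(RecordIndexEntry(
            header=cur_header,
            header_start=cur_hstart,
            seq_start=cur_sstart,
            seq_end=seq_end,
            length_bases=layout.total_bases,
            layout=layout,
        ))

    pos = 0
    while pos < n:
        nl = data.find(b"\n", pos)
        end = n if nl == -1 else nl
        if data[pos:pos + 1] == b">":
            if cur_header is not None:
                close(pos)
            header = parse_header_line(bytes(data[pos:end]))
            if header.id in seen:
                raise DuplicateId(f"duplicate sequence id {header.id!r}")
            seen.add(header.id)
            cur_header = header
            cur_hstart = pos
            cur_sstart = min(end + 1, n)
            cur_lengths = []
        elif cur_header is None:
            if end == pos:  # blank line before the first header
                preamble_end = min(end + 1, n)
            else:
                raise NotFasta("first non-blank line does not start with '>'")
        else:
            cur_lengths.append(end - pos)
        pos = end + 1

    if cur_header is not None:
        close(n)
    return FastaIndex(records, source_size=n, preamble=bytes(data[:preamble_end]))


@dataclass(frozen=True)
class Region:
    """A 1-based, closed subsequence interval on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise InvalidRegion(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise InvalidRegion(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_TAIL = re.compile(r"(\d+)-(\d+)\Z")


def parse_region(text: str, known_ids=None) -> Region:
    """Parse ``ID:START-END`` (1-based, closed interval).

    The split happens at the *last* ``:`` whose suffix parses as
    ``START-END``, so IDs containing ``:`` still resolve; when ``known_ids``
    is given, ties are broken in favor of the longest candidate ID that
    actually exists.
    """
    candidates: list[tuple[str, int, int]] = []
    i = text.find(":")
    while i != -1:
        m = _TAIL.match(text, i + 1)
        if m and i > 0:
            candidates.append((text[:i], int(m.group(1)), int(m.group(2))))
        i = text.find(":", i + 1)
    if not candidates:
        raise InvalidRegion(f"not an ID:START-END region: {text!r}")
    chosen = None
    if known_ids is not None:
        existing = [c for c in candidates if c[0] in known_ids]
        if existing:
            chosen = max(existing, key=lambda c: len(c[0]))
    if chosen is None:
        chosen = candidates[-1]  # last ':' → longest prefix
    seq_id, start, end = chosen
    return Region(seq_id=seq_id, start=start, end=end)


def format_region(region: Region) -> str:
    return f"{region.seq_id}:{region.start}-{region.end}"
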