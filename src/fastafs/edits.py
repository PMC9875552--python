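"""Write-back edit log over a mounted multiFASTA.

Mutations (rename / delete / overwrite / append) are staged in memory and
visible immediately through the *effective index*; the on-disk file is only
rewritten on :meth:`EditSession.flush` — triggered explicitly, by fsync /
unmount at the VFS layer, or automatically when the staged payload would
exceed the cache budget (500 MiB by default).

Flushing writes the whole effective file to a temporary sibling and then
atomically replaces the original, so a crash mid-flush leaves the mounted
file untouched.  Records that were never edited are copied as verbatim byte
spans: wrapping, padding, gaps and blank lines survive bit-exact.  Edited and
appended records keep the caller's bytes as written (no re-wrapping), gaining
only a terminal newline when the payload lacks one so the next header starts
at column 0.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterator

from .access import (
    DEFAULT_CACHE_BYTES,
    BackendKind,
    ByteSource,
    RamSource,
    open_source,
    read_raw,
    read_subsequence,
)
from .errors import (
    AlreadyExists,
    DuplicateId,
    FastaFsError,
    InvalidSequencePayload,
    NotFound,
    StorageError,
)
from .model import (
    FastaHeader,
    FastaIndex,
    LineLayout,
    RecordIndexEntry,
    Region,
    parse_header_line,
    scan_multifasta,
    validate_id_bytes,
)

logger = logging.getLogger(__name__)

_COPY_CHUNK = 8 * 2 ** 20  # span-copy granularity during flush


# --------------------------------------------------------------------------
# staged operations

@dataclass(frozen=True)
class Rename:
    old_id: str
    new_id: str


@dataclass(frozen=True)
class Delete:
    id: str


@dataclass(frozen=True)
class Overwrite:
    id: str
    data: bytes


@dataclass(frozen=True)
class Append:
    #: (raw_header_bytes, body_bytes) per appended record
    records: tuple[tuple[bytes, bytes], ...]


EditOp = Rename | Delete | Overwrite | Append


def validate_sequence_payload(data: bytes) -> None:
    """Reject sequence bytes that would corrupt FASTA structure on flush."""
    if b"\r" in data:
        raise InvalidSequencePayload("sequence payload contains '\\r'")
    if data.startswith(b">") or b"\n>" in data:
        raise InvalidSequencePayload(
            "sequence payload contains a line starting with '>'")


def _normalize_body(data: bytes) -> bytes:
    return data if (not data or data.endswith(b"\n")) else data + b"\n"


def _body_layout(body: bytes) -> LineLayout:
    if not body:
        return LineLayout.from_lengths([])
    lines = body.split(b"\n")
    if lines and lines[-1] == b"":
        lines.pop()
    return LineLayout.from_lengths(len(l) for l in lines)


class _Record:
    """One record of the effective file.

    ``entry`` points at the baseline on-disk record (None for records
    appended since the last flush); ``staged`` holds replacement body bytes
    (None while the on-disk body is current).  The header is always the
    *effective* one — renames update it in place.
    """

    __slots__ = ("header", "entry", "staged", "_staged_entry")

    def __init__(self, header: FastaHeader, entry: RecordIndexEntry | None,
                 staged: bytes | None = None):
        self.header = header
        self.entry = entry
        self.staged = staged
        self._staged_entry: RecordIndexEntry | None = None

    @property
    def renamed(self) -> bool:
        return self.entry is not None and self.header.raw != self.entry.header.raw

    @property
    def pristine(self) -> bool:
        """Body and header both still verbatim on disk."""
        return self.entry is not None and self.staged is None and not self.renamed

    def set_staged(self, body: bytes) -> None:
        self.staged = _normalize_body(body)
        self._staged_entry = None

    def staged_entry(self) -> RecordIndexEntry:
        """A pseudo index entry addressing the staged body (offset 0)."""
        if self._staged_entry is None:
            layout = _body_layout(self.staged)
            self._staged_entry = RecordIndexEntry(
                header=self.header, header_start=0, seq_start=0,
                seq_end=len(self.staged), length_bases=layout.total_bases,
                layout=layout)
        return self._staged_entry

    def length_bases(self) -> int:
        if self.staged is not None:
            return self.staged_entry().length_bases
        return self.entry.length_bases

    def body_nbytes(self) -> int:
        if self.staged is not None:
            return len(self.staged)
        return self.entry.body_nbytes


# --------------------------------------------------------------------------
# effective index (edit-aware view shared by stats/vfs)

@dataclass(frozen=True)
class EffectiveEntry:
    """Snapshot of one effective record with projected post-flush offsets."""

    header: FastaHeader
    length_bases: int
    seq_start: int
    seq_end: int


class EffectiveIndex:
    """Ordered, edit-aware counterpart of :class:`FastaIndex`."""

    def __init__(self, entries: list[EffectiveEntry], source_size: int,
                 preamble: bytes = b""):
        self._entries = entries
        self._by_id = {e.header.id: e for e in entries}
        self.source_size = source_size
        self.preamble = preamble

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[EffectiveEntry]:
        return iter(self._entries)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __getitem__(self, seq_id: str) -> EffectiveEntry:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise NotFound(f"no sequence named {seq_id!r}") from None

    def ids(self) -> list[str]:
        return [e.header.id for e in self._entries]


# --------------------------------------------------------------------------
# the session

class EditSession:
    """A mounted multiFASTA plus its pending edit log.

    Parameters
    ----------
    path:
        File to mount.  ``None`` mounts an in-memory buffer (``data``),
        useful for tests and dry runs; flushing then rewrites the buffer.
    backend:
        Byte-access backend (mmap / seek-read / full RAM).
    budget_bytes:
        Staged-payload budget; staging past it triggers an automatic flush
        first.  Defaults to 500 MiB.
    """

    def __init__(self, path: str | os.PathLike | None = None, *,
                 backend: BackendKind = BackendKind.MMAP,
                 budget_bytes: int = DEFAULT_CACHE_BYTES,
                 data: bytes | None = None):
        if budget_bytes <= 0:
            raise ValueError("cache budget must be positive")
        self.path = os.fspath(path) if path is not None else None
        self.backend = backend
        self.budget_bytes = budget_bytes
        if self.path is not None:
            self.source: ByteSource = open_source(self.path, backend)
            self._open_stat = self._stat()
        else:
            self.source = RamSource(data if data is not None else b"")
            self._open_stat = None
        self.index = scan_multifasta(self.source.view())
        self._records: list[_Record] = []
        self._by_id: dict[str, _Record] = {}
        self._rebuild_from_index()
        self.ops: list[EditOp] = []
        self.payload_bytes = 0
        self.flush_count = 0
        self.autoflush_count = 0

    # -- lifecycle ---------------------------------------------------------

    def _stat(self):
        try:
            st = os.stat(self.path)
            return (st.st_size, st.st_mtime_ns)
        except OSError:
            return None

    def _rebuild_from_index(self) -> None:
        self._records = [_Record(e.header, e) for e in self.index]
        self._by_id = {r.header.id: r for r in self._records}

    def close(self) -> None:
        self.source.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False

    # -- lookups -----------------------------------------------------------

    def _lookup(self, seq_id: str) -> _Record:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise NotFound(f"no sequence named {seq_id!r}") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def ids(self) -> list[str]:
        return [r.header.id for r in self._records]

    @property
    def dirty(self) -> bool:
        return bool(self.ops)

    def memory_footprint(self) -> int:
        """Bytes of staged payload held in memory."""
        return self.payload_bytes

    # -- reads (edit-aware) ------------------------------------------------

    def raw(self, seq_id: str) -> bytes:
        """Verbatim body bytes of a sequence (newlines included)."""
        rec = self._lookup(seq_id)
        if rec.staged is not None:
            return rec.staged
        return read_raw(self.source, rec.entry)

    def fasta(self, seq_id: str) -> bytes:
        """The sequence as a standalone single-record FASTA."""
        rec = self._lookup(seq_id)
        return b">" + rec.header.raw + b"\n" + (
            rec.staged if rec.staged is not None
            else read_raw(self.source, rec.entry))

    def subsequence(self, seq_id: str, region: Region) -> bytes:
        """1-based closed-interval subsequence, newline-free."""
        rec = self._lookup(seq_id)
        if rec.staged is not None:
            return read_subsequence(RamSource(rec.staged), rec.staged_entry(),
                                    region, check_id=False)
        return read_subsequence(self.source, rec.entry, region, check_id=False)

    def length(self, seq_id: str) -> int:
        return self._lookup(seq_id).length_bases()

    def effective_index(self) -> EffectiveIndex:
        """Snapshot of the edit-aware index with projected byte offsets."""
        entries: list[EffectiveEntry] = []
        offset = len(self.index.preamble)
        last = len(self._records) - 1
        for i, rec in enumerate(self._records):
            if rec.pristine:
                header_len = rec.entry.seq_start - rec.entry.header_start
            else:
                header_len = 1 + len(rec.header.raw) + 1
            body_len = rec.body_nbytes()
            sep = 0 if (i == last or self._ends_with_newline(rec)) else 1
            seq_start = offset + header_len
            seq_end = seq_start + body_len + sep
            entries.append(EffectiveEntry(rec.header, rec.length_bases(),
                                          seq_start, seq_end))
            offset = seq_end
        return EffectiveIndex(entries, source_size=offset,
                              preamble=self.index.preamble)

    # -- staging -----------------------------------------------------------

    def stage_rename(self, old_id: str, new_id: str) -> None:
        rec = self._lookup(old_id)
        if new_id == old_id:
            return
        new_bytes = new_id.encode("utf-8", "surrogateescape")
        validate_id_bytes(new_bytes)
        if new_id in self._by_id:
            raise AlreadyExists(f"sequence {new_id!r} already exists")
        old_bytes = rec.header.id_bytes
        new_raw = new_bytes + rec.header.raw[len(old_bytes):]
        rec.header = FastaHeader(new_id, rec.header.description, new_raw)
        del self._by_id[old_id]
        self._by_id[new_id] = rec
        self.ops.append(Rename(old_id, new_id))

    def stage_delete(self, seq_id: str) -> None:
        rec = self._lookup(seq_id)
        self._records.remove(rec)
        del self._by_id[seq_id]
        self.ops.append(Delete(seq_id))

    def stage_overwrite(self, seq_id: str, data: bytes) -> None:
        if seq_id not in self._by_id:
            raise NotFound(f"no sequence named {seq_id!r}")
        validate_sequence_payload(data)
        self._maybe_autoflush(len(data))
        rec = self._lookup(seq_id)  # re-resolved: autoflush rebuilds records
        rec.set_staged(data)
        self.payload_bytes += len(rec.staged)
        self.ops.append(Overwrite(seq_id, rec.staged))

    def stage_append(self, payload: bytes) -> int:
        """Append the records of a FASTA payload; non-FASTA payloads are
        ignored with a log record.  Returns the number of records appended."""
        if not payload:
            logger.warning("append: empty payload ignored")
            return 0
        if not payload.startswith(b">"):
            logger.warning(
                "append: payload does not match the FASTA signature "
                "(first line must start with '>'); ignored")
            return 0
        try:
            sub = scan_multifasta(payload)
        except DuplicateId:
            raise
        except FastaFsError as exc:
            logger.warning("append: malformed FASTA payload ignored: %s", exc)
            return 0
        clashes = [e.header.id for e in sub if e.header.id in self._by_id]
        if clashes:
            raise DuplicateId(
                f"append would duplicate existing ids: {clashes}")
        self._maybe_autoflush(len(payload))
        added: list[tuple[bytes, bytes]] = []
        for entry in sub:
            body = _normalize_body(payload[entry.seq_start:entry.seq_end])
            rec = _Record(entry.header, entry=None, staged=None)
            rec.set_staged(body)
            self._records.append(rec)
            self._by_id[entry.header.id] = rec
            added.append((entry.header.raw, body))
            self.payload_bytes += len(body)
        self.ops.append(Append(tuple(added)))
        return len(sub)

    def create_empty(self, seq_id: str) -> None:
        """Create a new empty record at the end of the file."""
        idb = seq_id.encode("utf-8", "surrogateescape")
        validate_id_bytes(idb)
        if seq_id in self._by_id:
            raise AlreadyExists(f"sequence {seq_id!r} already exists")
        header = parse_header_line(b">" + idb)
        rec = _Record(header, entry=None, staged=None)
        rec.set_staged(b"")
        self._records.append(rec)
        self._by_id[seq_id] = rec
        self.ops.append(Append(((header.raw, b""),)))

    def _maybe_autoflush(self, incoming: int) -> None:
        if self.payload_bytes + incoming > self.budget_bytes:
            logger.info(
                "staged payload %d B + incoming %d B exceeds budget %d B; "
                "flushing", self.payload_bytes, incoming, self.budget_bytes)
            self.autoflush_count += 1
            self.flush()

    # -- serialization & flush --------------------------------------------

    def _ends_with_newline(self, rec: _Record) -> bool:
        if rec.staged is not None:
            return True if not rec.staged else rec.staged.endswith(b"\n")
        if rec.pristine:
            # last byte of the verbatim [header_start, seq_end) span
            return self.source.read_span(
                rec.entry.seq_end - 1, rec.entry.seq_end) == b"\n"
        # rendered header always ends with '\n'; inspect the body if any
        if rec.entry.body_nbytes == 0:
            return True
        return self.source.read_span(
            rec.entry.seq_end - 1, rec.entry.seq_end) == b"\n"

    def _iter_span(self, start: int, end: int) -> Iterator[bytes]:
        pos = start
        while pos < end:
            nxt = min(pos + _COPY_CHUNK, end)
            yield self.source.read_span(pos, nxt)
            pos = nxt

    def serialized_chunks(self) -> Iterator[bytes]:
        """The effective file as a stream of byte chunks."""
        if self.index.preamble:
            yield self.index.preamble
        last = len(self._records) - 1
        for i, rec in enumerate(self._records):
            if rec.pristine:
                yield from self._iter_span(rec.entry.header_start,
                                           rec.entry.seq_end)
            else:
                yield b">" + rec.header.raw + b"\n"
                if rec.staged is not None:
                    if rec.staged:
                        yield rec.staged
                else:
                    yield from self._iter_span(rec.entry.seq_start,
                                               rec.entry.seq_end)
            if i != last and not self._ends_with_newline(rec):
                yield b"\n"

    def render(self) -> bytes:
        """The effective file as one bytes object."""
        return b"".join(self.serialized_chunks())

    def flush(self) -> FastaIndex:
        """Propagate staged edits to the mounted file and rescan.

        Writes the effective file to a temporary sibling, fsyncs it, then
        atomically replaces the target; on failure the original is intact and
        the temporary is removed.  Always rewrites (identity when no ops are
        pending) and empties the edit log.
        """
        self.flush_count += 1
        if self.path is None:
            data = self.render()
            self.source.close()
            self.source = RamSource(data)
        else:
            if self._open_stat is not None and self._stat() != self._open_stat:
                logger.warning(
                    "%s changed on disk since it was opened; flushing anyway, "
                    "but integrity guarantees are void", self.path)
            tmp = f"{self.path}.fastafs_tmp.{os.getpid()}"
            try:
                with open(tmp, "wb") as fh:
                    for chunk in self.serialized_chunks():
                        fh.write(chunk)
                    fh.flush()
                    os.fsync(fh.fileno())
                os.replace(tmp, self.path)
            except OSError as exc:
                try:
                    os.unlink(tmp)
                except OSError:
                    pass
                raise StorageError(f"flush failed: {exc}") from exc
            self.source.close()
            self.source = open_source(self.path, self.backend)
            self._open_stat = self._stat()
        self.index = scan_multifasta(self.source.view())
        self._rebuild_from_index()
        self.ops = []
        self.payload_bytes = 0
        return self.index

    # -- op-log compaction -------------------------------------------------

    def compacted_ops(self) -> list[EditOp]:
        """A minimal op list equivalent to the pending log.

        Derived from the effective state as a diff against the baseline
        index: deletes, then collision-free renames (cycles broken through
        temporary ids), then overwrites, then one append.  Replaying it on a
        fresh session of the baseline file reproduces the effective file.
        """
        ops: list[EditOp] = []
        survivors = {r.entry.header.id: r for r in self._records
                     if r.entry is not None}
        for orig in self.index.ids():
            if orig not in survivors:
                ops.append(Delete(orig))
        current = set(survivors)
        pending = {old: r.header.id for old, r in survivors.items()
                   if r.header.id != old}
        tmp_n = 0
        while pending:
            progressed = False
            for old, new in list(pending.items()):
                if new not in current or new == old:
                    ops.append(Rename(old, new))
                    current.discard(old)
                    current.add(new)
                    del pending[old]
                    progressed = True
            if not progressed:  # rename cycle: detour via a temporary id
                old, new = next(iter(pending.items()))
                tmp = f"__fastafs_cycle_{tmp_n}"
                tmp_n += 1
                ops.append(Rename(old, tmp))
                current.discard(old)
                current.add(tmp)
                del pending[old]
                pending[tmp] = new
        for r in self._records:
            if r.entry is not None and r.staged is not None:
                ops.append(Overwrite(r.header.id, r.staged))
        appended = tuple((r.header.raw, r.staged) for r in self._records
                        if r.entry is None)
        if appended:
            ops.append(Append(appended))
        return ops

    def apply_ops(self, ops: list[EditOp]) -> None:
        """Replay an op list (used to test compaction equivalence)."""
        for op in ops:
            if isinstance(op, Rename):
                self.stage_rename(op.old_id, op.new_id)
            elif isinstance(op, Delete):
                self.stage_delete(op.id)
            elif isinstance(op, Overwrite):
                self.stage_overwrite(op.id, op.data)
            elif isinstance(op, Append):
                payload = b"".join(b">" + raw + b"\n" + _normalize_body(body)
                                   for raw, body in op.records)
                self.stage_append(payload)
            else:  # pragma: no cover - defensive
                raise TypeError(f"unknown op {op!r}")
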