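"""The mount-independent virtual tree.

Translates POSIX-like operations (lookup / readdir / read / write / create /
unlink / rename / truncate / fsync / release) on virtual nodes into
edit-aware reads and staged mutations of an :class:`~fastafs.edits.EditSession`.
The FUSE adapter binds this contract to the kernel; the test harness drives
it directly, so every behavior is exercised without mount privileges.

Layout of the tree::

    /
    ├── labels.txt     read-only header register
    ├── infos.txt      read-only human summary
    ├── infos.csv      read-only per-sequence table
    ├── seqs/<ID>.seq  read-write raw sequence bodies
    ├── fasta/<ID>.fa  read-only single-record FASTA views
    ├── append/        drop-box: files written here are appended, not kept
    └── get/           invisible namespace: read ID:START-END on the fly

Writes to ``seqs/`` and ``append/`` are buffered per open handle and applied
on release, because POSIX writes arrive in arbitrary chunks and a
half-written record must never become observable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .edits import EditSession
from .errors import (
    InvalidRegion,
    IsADirectory,
    NotADirectory,
    NotFound,
    OutOfRange,
    ReadOnlyNode,
)
from .model import parse_region
from .views import render_infos_csv, render_infos_txt, render_labels

ROOT_FILES = ("labels.txt", "infos.txt", "infos.csv")
ROOT_DIRS = ("seqs", "fasta", "append", "get")

SEQ_SUFFIX = ".seq"
FASTA_SUFFIX = ".fa"


class NodeKind(enum.Enum):
    DIRECTORY = "directory"
    STATIC_FILE = "static_file"
    SEQUENCE_FILE = "sequence_file"
    FASTA_FILE = "fasta_file"
    REGION_FILE = "dynamic_region_file"
    APPEND_SLOT = "append_slot"


@dataclass(frozen=True)
class NodeAttr:
    kind: NodeKind
    size: int
    writable: bool

    @property
    def is_dir(self) -> bool:
        return self.kind is NodeKind.DIRECTORY


@dataclass
class _Handle:
    kind: NodeKind           # SEQUENCE_FILE or APPEND_SLOT
    name: str                # sequence id, or drop-box slot name
    buffer: bytearray


def _strip(name: str, suffix: str) -> str:
    return name[: -len(suffix)] if name.endswith(suffix) else name


class FastaVfs:
    """Virtual filesystem over one :class:`EditSession`."""

    def __init__(self, session: EditSession):
        self.session = session
        self._handles: dict[int, _Handle] = {}
        self._next_handle = 1
        self._unmounted = False

    # -- path plumbing -----------------------------------------------------

    @staticmethod
    def _parts(path: str) -> list[str]:
        path = path.strip("/")
        return path.split("/") if path else []

    def _seq_id(self, name: str) -> str:
        return _strip(name, SEQ_SUFFIX)

    # -- attributes & listing ---------------------------------------------

    def getattr(self, path: str) -> NodeAttr:
        parts = self._parts(path)
        if not parts:
            return NodeAttr(NodeKind.DIRECTORY, 0, False)
        if len(parts) == 1:
            name = parts[0]
            if name in ROOT_DIRS:
                return NodeAttr(NodeKind.DIRECTORY, 0, name in ("seqs", "append"))
            if name in ROOT_FILES:
                return NodeAttr(NodeKind.STATIC_FILE,
                                len(self._render_static(name)), False)
            raise NotFound(f"no such node: {path!r}")
        if len(parts) == 2:
            top, name = parts
            if top == "seqs":
                seq_id = self._seq_id(name)
                if seq_id not in self.session:
                    raise NotFound(f"no sequence {seq_id!r}")
                return NodeAttr(NodeKind.SEQUENCE_FILE,
                                len(self.session.raw(seq_id)), True)
            if top == "fasta":
                seq_id = _strip(name, FASTA_SUFFIX)
                if seq_id not in self.session:
                    raise NotFound(f"no sequence {seq_id!r}")
                return NodeAttr(NodeKind.FASTA_FILE,
                                len(self.session.fasta(seq_id)), False)
            if top == "get":
                return NodeAttr(NodeKind.REGION_FILE,
                                len(self._read_region(name)), False)
            if top == "append":
                for h in self._handles.values():
                    if h.kind is NodeKind.APPEND_SLOT and h.name == name:
                        return NodeAttr(NodeKind.APPEND_SLOT,
                                        len(h.buffer), True)
                raise NotFound(f"no such node: {path!r}")
        raise NotFound(f"no such node: {path!r}")

    def listdir(self, path: str) -> list[str]:
        parts = self._parts(path)
        if not parts:
            return list(ROOT_FILES) + list(ROOT_DIRS)
        if len(parts) == 1:
            name = parts[0]
            if name == "seqs":
                return [i + SEQ_SUFFIX for i in self.session.ids()]
            if name == "fasta":
                return [i + FASTA_SUFFIX for i in self.session.ids()]
            if name in ("append", "get"):
                return []  # get/ serves reads without listing anything
            if name in ROOT_FILES:
                raise NotADirectory(f"{path!r} is not a directory")
        raise NotFound(f"no such directory: {path!r}")

    # -- reading -----------------------------------------------------------

    def _render_static(self, name: str) -> bytes:
        index = self.session.effective_index()
        if name == "labels.txt":
            text = render_labels(index)
        elif name == "infos.csv":
            text = render_infos_csv(index)
        elif name == "infos.txt":
            text = render_infos_txt(index, source_path=self.session.path or "",
                                    source_size=index.source_size)
        else:  # pragma: no cover - guarded by callers
            raise NotFound(name)
        return text.encode("utf-8", "surrogateescape")

    def _read_region(self, name: str) -> bytes:
        try:
            region = parse_region(name, known_ids=self.session)
            return self.session.subsequence(region.seq_id, region)
        except (InvalidRegion, OutOfRange, NotFound) as exc:
            raise NotFound(f"no such region file: {name!r} ({exc})") from exc

    def read_full(self, path: str) -> bytes:
        parts = self._parts(path)
        if not parts or (len(parts) == 1 and parts[0] in ROOT_DIRS):
            raise IsADirectory(f"{path!r} is a directory")
        if len(parts) == 1 and parts[0] in ROOT_FILES:
            return self._render_static(parts[0])
        if len(parts) == 2:
            top, name = parts
            if top == "seqs":
                seq_id = self._seq_id(name)
                if seq_id not in self.session:
                    raise NotFound(f"no sequence {seq_id!r}")
                return self.session.raw(seq_id)
            if top == "fasta":
                seq_id = _strip(name, FASTA_SUFFIX)
                if seq_id not in self.session:
                    raise NotFound(f"no sequence {seq_id!r}")
                return self.session.fasta(seq_id)
            if top == "get":
                return self._read_region(name)
            if top == "append":
                return b""
        raise NotFound(f"no such node: {path!r}")

    def read(self, path: str, offset: int = 0, size: int | None = None) -> bytes:
        """Read ``size`` bytes at ``offset``; reads at/after EOF return b''."""
        data = self.read_full(path)
        if offset >= len(data):
            return b""
        end = len(data) if size is None else min(offset + size, len(data))
        return data[offset:end]

    # -- writing -----------------------------------------------------------

    def create(self, path: str) -> int:
        """Create a node: an empty record under seqs/, a drop-box slot under
        append/.  Returns a write handle."""
        parts = self._parts(path)
        if len(parts) != 2 or parts[0] not in ("seqs", "append"):
            raise ReadOnlyNode(f"cannot create {path!r}")
        top, name = parts
        if top == "seqs":
            seq_id = self._seq_id(name)
            self.session.create_empty(seq_id)
            return self._open(NodeKind.SEQUENCE_FILE, seq_id, b"")
        return self._open(NodeKind.APPEND_SLOT, name, b"")

    def open_write(self, path: str, truncate: bool = False) -> int:
        parts = self._parts(path)
        if len(parts) == 2 and parts[0] == "seqs":
            seq_id = self._seq_id(parts[1])
            if seq_id not in self.session:
                raise NotFound(f"no sequence {seq_id!r}")
            initial = b"" if truncate else self.session.raw(seq_id)
            return self._open(NodeKind.SEQUENCE_FILE, seq_id, initial)
        if len(parts) == 2 and parts[0] == "append":
            return self._open(NodeKind.APPEND_SLOT, parts[1], b"")
        raise ReadOnlyNode(f"{path!r} is not writable")

    def _open(self, kind: NodeKind, name: str, initial: bytes) -> int:
        handle = self._next_handle
        self._next_handle += 1
        self._handles[handle] = _Handle(kind, name, bytearray(initial))
        return handle

    def write(self, handle: int, data: bytes, offset: int) -> int:
        buf = self._handles[handle].buffer
        if offset > len(buf):
            buf.extend(b"\x00" * (offset - len(buf)))
        buf[offset:offset + len(data)] = data
        return len(data)

    def truncate_handle(self, handle: int, size: int) -> None:
        buf = self._handles[handle].buffer
        if size < len(buf):
            del buf[size:]
        else:
            buf.extend(b"\x00" * (size - len(buf)))

    def truncate(self, path: str, size: int) -> None:
        """Path-based truncate: resize an open buffer if one exists for the
        path, else stage the resized body immediately."""
        parts = self._parts(path)
        if len(parts) == 2 and parts[0] == "seqs":
            seq_id = self._seq_id(parts[1])
            for h in self._handles.values():
                if h.kind is NodeKind.SEQUENCE_FILE and h.name == seq_id:
                    if size < len(h.buffer):
                        del h.buffer[size:]
                    else:
                        h.buffer.extend(b"\x00" * (size - len(h.buffer)))
                    return
            body = self.session.raw(seq_id)
            body = body[:size] + b"\x00" * max(0, size - len(body))
            self.session.stage_overwrite(seq_id, body)
            return
        raise ReadOnlyNode(f"{path!r} is not writable")

    def release(self, handle: int) -> int:
        """Close a write handle, applying its buffer.

        seqs/ buffers become a staged overwrite; append/ buffers become a
        staged append (the drop-box name is not retained).  Returns the
        number of records appended (0 for sequence overwrites)."""
        h = self._handles.pop(handle)
        if h.kind is NodeKind.SEQUENCE_FILE:
            self.session.stage_overwrite(h.name, bytes(h.buffer))
            return 0
        return self.session.stage_append(bytes(h.buffer))

    # -- namespace mutations ----------------------------------------------

    def unlink(self, path: str) -> None:
        parts = self._parts(path)
        if len(parts) == 2 and parts[0] == "seqs":
            self.session.stage_delete(self._seq_id(parts[1]))
            return
        if len(parts) == 2 and parts[0] == "append":
            raise NotFound(f"no such node: {path!r}")
        # metadata files, fasta/ views and get/ are read-only
        self.getattr(path)  # surfaces NotFound for unknown paths first
        raise ReadOnlyNode(f"cannot unlink read-only node {path!r}")

    def rename(self, src: str, dst: str) -> None:
        """mv semantics: within seqs/ renames the sequence; moving a
        sequence out of seqs/ removes it from the mounted file."""
        sparts = self._parts(src)
        if len(sparts) != 2 or sparts[0] != "seqs":
            raise ReadOnlyNode(f"cannot rename {src!r}")
        src_id = self._seq_id(sparts[1])
        dparts = self._parts(dst)
        if len(dparts) == 2 and dparts[0] == "seqs":
            self.session.stage_rename(src_id, self._seq_id(dparts[1]))
        else:
            self.session.stage_delete(src_id)

    # -- synchronization ---------------------------------------------------

    def fsync(self, path: str = "/") -> None:
        """Propagate staged edits to the mounted file (fsync/fsyncdir)."""
        self.session.flush()

    def flush_all(self) -> None:
        self.session.flush()

    def unmount(self) -> None:
        """Flush pending edits and mark the tree closed (idempotent)."""
        if self._unmounted:
            return
        self.flush_all()
        self.session.close()
        self._unmounted = True
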