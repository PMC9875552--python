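"""Byte- and base-level random access through interchangeable backends.

Three backends satisfy one read contract: memory-mapped access (default,
fastest for repeated random reads through the OS page cache), plain
seek-and-read (smallest resident footprint), and whole-file in-RAM caching
(fastest once loaded, costs as much memory as the file).  On top of the raw
byte contract, this module does the wrapping-aware base→byte arithmetic that
turns 1-based closed intervals into byte spans of the mounted file.
"""

from __future__ import annotations

import enum
import mmap
import os
from typing import BinaryIO

from .errors import OutOfRange, StorageError
from .model import RecordIndexEntry, Region

#: Default write-back cache budget: 500 MiB.
DEFAULT_CACHE_BYTES = 500 * 2 ** 20

#: Fraction of available memory the RAM backend may claim.
_RAM_HEADROOM = 0.8


class BackendKind(enum.Enum):
    MMAP = "mmap"
    SEEK_READ = "file"
    FULL_RAM = "ram"


class ByteSource:
    """Abstract random-access byte window over the mounted file."""

    total_size: int

    def read_span(self, start: int, end: int) -> bytes:
        """Return exactly ``end - start`` bytes for 0 <= start <= end <= total_size."""
        raise NotImplementedError

    def view(self):
        """A bytes-like object over the whole source (used for scanning)."""
        return self.read_span(0, self.total_size)

    def close(self) -> None:
        pass

    def _check(self, start: int, end: int) -> None:
        if not (0 <= start <= end <= self.total_size):
            raise OutOfRange(
                f"span [{start}, {end}) outside source of {self.total_size} bytes")

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
        return False


class RamSource(ByteSource):
    """Whole content held in memory (also used for staged in-memory bodies)."""

    def __init__(self, data: bytes):
        self._data = data
        self.total_size = len(data)

    def read_span(self, start: int, end: int) -> bytes:
        self._check(start, end)
        return self._data[start:end]

    def view(self):
        return self._data


class MmapSource(ByteSource):
    def __init__(self, path: str):
        self._fh: BinaryIO = open(path, "rb")
        self.total_size = os.fstat(self._fh.fileno()).st_size
        # mmap rejects empty files; degrade to an empty buffer
        self._map = (mmap.mmap(self._fh.fileno(), 0, access=mmap.ACCESS_READ)
                     if self.total_size else None)

    def read_span(self, start: int, end: int) -> bytes:
        self._check(start, end)
        return self._map[start:end] if self._map is not None else b""

    def view(self):
        return self._map if self._map is not None else b""

    def close(self) -> None:
        if self._map is not None:
            self._map.close()
            self._map = None
        if not self._fh.closed:
            self._fh.close()


class SeekReadSource(ByteSource):
    def __init__(self, path: str):
        self._fh: BinaryIO = open(path, "rb")
        self.total_size = os.fstat(self._fh.fileno()).st_size

    def read_span(self, start: int, end: int) -> bytes:
        self._check(start, end)
        self._fh.seek(start)
        return self._fh.read(end - start)

    def view(self):
        self._fh.seek(0)
        return self._fh.read()

    def close(self) -> None:
        if not self._fh.closed:
            self._fh.close()


def available_memory_bytes() -> int | None:
    """Best-effort MemAvailable from /proc/meminfo; None when unknown."""
    try:
        with open("/proc/meminfo") as fh:
            for line in fh:
                if line.startswith("MemAvailable:"):
                    return int(line.split()[1]) * 1024
    except OSError:
        pass
    return None


def open_source(path: str | os.PathLike, kind: BackendKind = BackendKind.MMAP) -> ByteSource:
    """Open the mounted file under the selected backend."""
    path = os.fspath(path)
    try:
        if kind is BackendKind.MMAP:
            return MmapSource(path)
        if kind is BackendKind.SEEK_READ:
            return SeekReadSource(path)
        if kind is BackendKind.FULL_RAM:
            size = os.path.getsize(path)
            avail = available_memory_bytes()
            if avail is not None and size > _RAM_HEADROOM * avail:
                raise StorageError(
                    f"refusing to load {size} bytes into RAM "
                    f"(only {avail} bytes available)")
            with open(path, "rb") as fh:
                return RamSource(fh.read())
    except OSError as exc:
        raise StorageError(f"cannot open {path!r}: {exc}") from exc
    raise ValueError(f"unknown backend {kind!r}")


def base_to_byte(entry: RecordIndexEntry, base: int) -> int:
    """Absolute byte offset of the 1-based ``base``-th base of a record."""
    if not 1 <= base <= entry.length_bases:
        raise OutOfRange(
            f"base {base} outside 1..{entry.length_bases} of {entry.header.id!r}")
    return entry.seq_start + entry.layout.base_offset(base - 1)


def read_subsequence(src: ByteSource, entry: RecordIndexEntry, region: Region,
                     *, check_id: bool = True) -> bytes:
    """The bases of ``region`` (1-based, closed) with newlines removed.

    Out-of-range coordinates are a hard error — reads never clamp, because a
    silently truncated subsequence corrupts downstream coordinates.
    """
    if check_id and region.seq_id != entry.header.id:
        raise ValueError(
            f"region names {region.seq_id!r} but entry is {entry.header.id!r}")
    if region.end > entry.length_bases:
        raise OutOfRange(
            f"region {region.start}-{region.end} beyond "
            f"{entry.length_bases}-base sequence {entry.header.id!r}")
    a = base_to_byte(entry, region.start)
    b = base_to_byte(entry, region.end) + 1
    return src.read_span(a, b).replace(b"\n", b"")


def read_raw(src: ByteSource, entry: RecordIndexEntry) -> bytes:
    """Verbatim body span of the record, internal newlines included."""
    return src.read_span(entry.seq_start, entry.seq_end)


def render_fasta(src: ByteSource, entry: RecordIndexEntry) -> bytes:
    """The record as a standalone single-sequence FASTA file."""
    return b">" + entry.header.raw + b"\n" + read_raw(src, entry)
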