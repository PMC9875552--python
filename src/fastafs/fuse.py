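"""Bind the virtual tree to the host kernel through FUSE.

This adapter contains no filesystem semantics of its own: it maps FUSE
callbacks one-to-one onto the :class:`~fastafs.vfs.FastaVfs` contract and
package errors onto errno values.  The ``fusepy`` binding is imported lazily
so the library, CLI parsing and the whole in-process test harness work on
hosts without FUSE; actually mounting requires ``pip install fastafs[fuse]``
and a kernel with the FUSE device.
"""

from __future__ import annotations

import errno
import logging
import os
import stat
import sys
import time
from dataclasses import dataclass, field

from .access import DEFAULT_CACHE_BYTES, BackendKind
from .edits import EditSession
from .errors import (
    AlreadyExists,
    FastaFsError,
    InvalidSequencePayload,
    IsADirectory,
    MountError,
    NotADirectory,
    NotFound,
    ReadOnlyNode,
    StorageError,
)
from .vfs import FastaVfs

logger = logging.getLogger(__name__)

_ERRNO = {
    NotFound: errno.ENOENT,
    ReadOnlyNode: errno.EACCES,
    AlreadyExists: errno.EEXIST,
    IsADirectory: errno.EISDIR,
    NotADirectory: errno.ENOTDIR,
    InvalidSequencePayload: errno.EINVAL,
    StorageError: errno.EIO,
}


@dataclass
class MountConfig:
    """Runtime options of one mount."""

    fasta_path: str
    mount_point: str
    backend: BackendKind = BackendKind.MMAP
    cache_budget_bytes: int = DEFAULT_CACHE_BYTES
    foreground: bool = False
    verbosity: int = 0
    extra_fuse_options: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.cache_budget_bytes <= 0:
            raise MountError("cache budget must be positive")
        if not os.path.isfile(self.fasta_path):
            raise MountError(f"not a readable file: {self.fasta_path!r}")


def _load_fuse():
    try:
        import fuse  # fusepy
        return fuse
    except ImportError as exc:
        raise MountError(
            "kernel mounting requires the 'fusepy' package and a FUSE-capable "
            "kernel; install with 'pip install fastafs[fuse]'. The library "
            "API (fastafs.vfs.FastaVfs) works without it.") from exc


def build_filesystem(config: MountConfig) -> FastaVfs:
    """Parse and index the file, returning the in-process virtual tree.

    Raised parse errors abort before anything touches FUSE."""
    config.validate()
    session = EditSession(config.fasta_path, backend=config.backend,
                          budget_bytes=config.cache_budget_bytes)
    return FastaVfs(session)


def _make_operations(vfs: FastaVfs, fuse_module):
    """Build the fusepy Operations object delegating to ``vfs``."""

    FuseOSError = fuse_module.FuseOSError

    def to_errno(exc: FastaFsError) -> "FuseOSError":
        for etype, eno in _ERRNO.items():
            if isinstance(exc, etype):
                return FuseOSError(eno)
        return FuseOSError(errno.EIO)

    now = time.time()

    class Adapter(fuse_module.Operations):  # pragma: no cover - needs a kernel
        def _attr(self, path):
            try:
                attr = vfs.getattr(path)
            except FastaFsError as exc:
                raise to_errno(exc) from exc
            if attr.is_dir:
                mode = stat.S_IFDIR | 0o755
            else:
                mode = stat.S_IFREG | (0o644 if attr.writable else 0o444)
            return {"st_mode": mode, "st_size": attr.size, "st_nlink": 1,
                    "st_uid": os.getuid(), "st_gid": os.getgid(),
                    "st_atime": now, "st_mtime": now, "st_ctime": now}

        getattr = lambda self, path, fh=None: self._attr(path)

        def readdir(self, path, fh):
            try:
                return [".", ".."] + vfs.listdir(path)
            except FastaFsError as exc:
                raise to_errno(exc) from exc

        def read(self, path, size, offset, fh):
            try:
                return vfs.read(path, offset, size)
            except FastaFsError as exc:
                raise to_errno(exc) from exc

        def create(self, path, mode, fi=None):
            try:
                return vfs.create(path)
            except FastaFsError as exc:
                raise to_errno(exc) from exc

        def open(self, path, flags):
            writing = flags & (os.O_WRONLY | os.O_RDWR)
            if not writing:
                return 0
            try:
                return vfs.open_write(path, truncate=bool(flags & os.O_TRUNC))
            except FastaFsError as exc:
                raise to_errno(exc) from exc

        def write(self, path, data, offset, fh):
            try:
                return vfs.write(fh, data, offset)
            except (FastaFsError, KeyError) as exc:
                raise to_errno(exc) if isinstance(exc, FastaFsError) \
                    else FuseOSError(errno.EBADF) from exc

        def truncate(self, path, length, fh=None):
            try:
                vfs.truncate(path, length)
            except FastaFsError as exc:
                raise to_errno(exc) from exc

        def release(self, path, fh):
            if fh:
                try:
                    vfs.release(fh)
                except KeyError:
                    pass
                except FastaFsError as exc:
                    raise to_errno(exc) from exc
            return 0

        def unlink(self, path):
            try:
                vfs.unlink(path)
            except FastaFsError as exc:
                raise to_errno(exc) from exc

        def rename(self, old, new):
            try:
                vfs.rename(old, new)
            except FastaFsError as exc:
                raise to_errno(exc) from exc

        def fsync(self, path, datasync, fh):
            try:
                vfs.fsync(path)
            except FastaFsError as exc:
                raise to_errno(exc) from exc
            return 0

        fsyncdir = fsync
        flush = lambda self, path, fh: 0

        def destroy(self, path):
            try:
                vfs.unmount()
            except FastaFsError:
                logger.exception("flush on unmount failed")

    return Adapter()


def configure_logging(verbosity: int) -> None:
    level = (logging.WARNING, logging.INFO, logging.DEBUG)[min(verbosity, 2)]
    logging.basicConfig(
        level=level, stream=sys.stderr,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s")


def mount(config: MountConfig) -> None:
    """Mount ``config.fasta_path`` at ``config.mount_point`` and serve until
    unmounted; unmounting flushes pending edits, then the call returns.

    Foreground mode stays attached to the shell and streams operation logs;
    background mode (the default) detaches.
    """
    configure_logging(config.verbosity)
    vfs = build_filesystem(config)  # parse errors abort before mounting
    if not os.path.isdir(config.mount_point):
        raise MountError(f"mount point is not a directory: {config.mount_point!r}")
    fuse_module = _load_fuse()
    ops = _make_operations(vfs, fuse_module)
    try:
        fuse_module.FUSE(ops, config.mount_point,
                         foreground=config.foreground, nothreads=True,
                         fsname="fastafs", **config.extra_fuse_options)
    except RuntimeError as exc:  # fusepy wraps mount failures this way
        raise MountError(f"mount failed: {exc}") from exc
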