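"""Exception hierarchy.

Every error raised by this package derives from :class:`FastaFsError`, so
callers (and the FUSE adapter, which maps these onto errno values) can catch
one base class.
"""


class FastaFsError(Exception):
    """Base class for all fastafs errors."""


class InvalidHeader(FastaFsError):
    """A header line is malformed (e.g. a bare ``>`` with no ID)."""


class InvalidId(FastaFsError):
    """A sequence ID is not usable as a filename component."""


class NotFasta(FastaFsError):
    """The input does not carry the FASTA signature (first line ``>``...)."""


class NonUnixLineEndings(FastaFsError):
    """A carriage return was found; only UNIX ``\\n`` delimiters are supported."""


class DuplicateId(FastaFsError):
    """Two records share the same ID."""


class InvalidRegion(FastaFsError):
    """A region string does not parse as ``ID:START-END`` with 1 <= START <= END."""


class OutOfRange(FastaFsError):
    """A base coordinate lies outside the sequence."""


class NotFound(FastaFsError):
    """No such sequence / virtual node."""


class AlreadyExists(FastaFsError):
    """Target ID already present."""


class InvalidSequencePayload(FastaFsError):
    """Sequence bytes that would corrupt the FASTA structure on flush."""


class ReadOnlyNode(FastaFsError):
    """Write/unlink attempted on a read-only virtual node."""


class NotADirectory(FastaFsError):
    """Directory operation on a file node."""


class IsADirectory(FastaFsError):
    """File operation on a directory node."""


class StorageError(FastaFsError):
    """Underlying I/O failure (open, read, write, replace)."""


class MountError(FastaFsError):
    """The filesystem could not be mounted."""


class InvalidSpec(FastaFsError):
    """A synthetic-fixture specification is self-contradictory."""
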