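"""Shared fixtures and independent naive oracles.

The oracles deliberately share no code with the package: they parse by
splitting on newlines / header starts and are used to cross-check the
byte-offset index, subsequence arithmetic and the flush serializer.
"""

from __future__ import annotations

import re

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def naive_parse(data: bytes) -> list[tuple[str, str | None, bytes]]:
    """(id, description, newline-stripped sequence) per record, the dumb way."""
    records: list[list] = []
    cur = None
    for line in data.split(b"\n"):
        if line.startswith(b">"):
            body = line[1:]
            cuts = [i for i in (body.find(b" "), body.find(b"\t")) if i != -1]
            if cuts:
                cut = min(cuts)
                ident, desc = body[:cut], body[cut + 1:].lstrip(b" \t")
                desc_s = desc.decode("utf-8", "surrogateescape")
            else:
                ident, desc_s = body, None
            cur = [ident.decode("utf-8", "surrogateescape"), desc_s, bytearray()]
            records.append(cur)
        elif cur is not None:
            cur[2].extend(line)
    return [(i, d, bytes(s)) for i, d, s in records]


def split_record_chunks(data: bytes) -> tuple[bytes, list[bytes]]:
    """(preamble, verbatim per-record byte chunks), via a regex header scan."""
    starts = [m.start() for m in re.finditer(rb"^>", data, re.M)]
    if not starts:
        return data, []
    preamble = data[:starts[0]]
    bounds = starts + [len(data)]
    return preamble, [data[a:b] for a, b in zip(bounds, bounds[1:])]


def chunk_id(chunk: bytes) -> str:
    first = chunk.split(b"\n", 1)[0][1:]
    for ws in (b" ", b"\t"):
        cut = first.find(ws)
        if cut != -1:
            first = first[:cut]
    return first.decode("utf-8", "surrogateescape")


def apply_ops_naive(data: bytes, ops: list[tuple]) -> bytes:
    """Brute-force edit oracle over verbatim record chunks.

    ops: ("delete", id) | ("rename", old, new) | ("overwrite", id, body)
         | ("append", payload).  Bodies/payloads are expected to end with a
    newline (the engine normalizes; the oracle stays dumb).
    """
    preamble, chunks = split_record_chunks(data)
    for op in ops:
        kind = op[0]
        if kind == "delete":
            chunks = [c for c in chunks if chunk_id(c) != op[1]]
        elif kind == "rename":
            out = []
            for c in chunks:
                if chunk_id(c) == op[1]:
                    first, _, rest = c.partition(b"\n")
                    old = op[1].encode("utf-8", "surrogateescape")
                    new = op[2].encode("utf-8", "surrogateescape")
                    first = b">" + new + first[1 + len(old):]
                    c = first + b"\n" + rest
                out.append(c)
            chunks = out
        elif kind == "overwrite":
            out = []
            for c in chunks:
                if chunk_id(c) == op[1]:
                    first = c.split(b"\n", 1)[0]
                    c = first + b"\n" + op[2]
                out.append(c)
            chunks = out
        elif kind == "append":
            _, new_chunks = split_record_chunks(op[1])
            if chunks and not chunks[-1].endswith(b"\n"):
                chunks[-1] += b"\n"
            chunks.extend(new_chunks)
        else:
            raise ValueError(kind)
    # records glued back; any chunk not ending in '\n' mid-list gets one
    body = b""
    for i, c in enumerate(chunks):
        if i < len(chunks) - 1 and not c.endswith(b"\n"):
            c += b"\n"
        body += c
    return preamble + body


@pytest.fixture
def write_fasta(tmp_path):
    """Write bytes to a temp .fa file, returning its path."""
    counter = [0]

    def _write(data: bytes):
        counter[0] += 1
        path = tmp_path / f"fixture_{counter[0]}.fa"
        path.write_bytes(data)
        return path

    return _write
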