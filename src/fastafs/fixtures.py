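"""Deterministic synthetic multiFASTA generator.

Produces every formatting feature the mount layer must tolerate — uniform,
heterogeneous or absent line wrapping, alignment gaps, empty sequences, blank
lines inside records, missing trailing newline, arbitrary alphabets — along
with the exact ground truth (ID, description, newline-stripped sequence) used
to build each record, so every test has an intrinsic oracle.  Sequences are
compositionally random: the generator emulates FASTA *formatting* diversity,
not biological content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import InvalidSpec

ALPHABETS: dict[str, bytes] = {
    "dna": b"ACGT",
    "protein": b"ACDEFGHIKLMNPQRSTVWY",
    # IUPAC ambiguity codes plus assorted printable bytes the format tolerates
    "any": b"ACGTUNRYSWKMBDHVacgtun*.#@!%&+=~0123456789",
}

WrapPolicy = Literal["unwrapped", "uniform", "heterogeneous", "mixed"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic multiFASTA."""

    seed: int = 0
    n_records: int = 10
    min_len: int = 0
    max_len: int = 200
    wrap: WrapPolicy = "uniform"
    wrap_width: int = 60
    gap_fraction: float = 0.0
    empty_prob: float = 0.0
    alphabet: str = "dna"
    description_prob: float = 0.5
    blank_line_prob: float = 0.0
    trailing_newline: bool = True
    ids: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_records < 0:
            raise InvalidSpec("n_records must be >= 0")
        if self.min_len < 0 or self.min_len > self.max_len:
            raise InvalidSpec(
                f"need 0 <= min_len <= max_len, got {self.min_len}..{self.max_len}")
        if self.wrap not in ("unwrapped", "uniform", "heterogeneous", "mixed"):
            raise InvalidSpec(f"unknown wrap policy {self.wrap!r}")
        if self.wrap_width < 1:
            raise InvalidSpec("wrap_width must be >= 1")
        if self.alphabet not in ALPHABETS:
            raise InvalidSpec(f"unknown alphabet {self.alphabet!r}")
        for name in ("gap_fraction", "empty_prob", "description_prob",
                     "blank_line_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpec(f"{name} must be in [0, 1], got {v}")
        if self.ids is not None and len(self.ids) != self.n_records:
            raise InvalidSpec("ids override must list one id per record")


@dataclass(frozen=True)
class FixtureRecord:
    """Ground truth for one generated record."""

    id: str
    description: str | None
    sequence: bytes  # newline-stripped, gaps included


def _random_sequence(rng: np.random.Generator, length: int,
                     alphabet: bytes, gap_fraction: float) -> bytes:
    if length == 0:
        return b""
    table = np.frombuffer(alphabet, dtype=np.uint8)
    seq = table[rng.integers(0, len(table), size=length)]
    if gap_fraction > 0.0:
        seq = seq.copy()
        seq[rng.random(length) < gap_fraction] = ord("-")
    return seq.tobytes()


def _line_widths(rng: np.random.Generator, length: int) -> list[int]:
    """Random heterogeneous widths (1..80) covering ``length`` bases."""
    widths: list[int] = []
    covered = 0
    while covered < length:
        chunk = rng.integers(1, 81, size=max(8, (length - covered) // 40 + 1))
        for w in chunk:
            widths.append(int(w))
            covered += int(w)
            if covered >= length:
                break
    if widths:
        widths[-1] -= covered - length
        if widths[-1] == 0:
            widths.pop()
    return widths


def _wrap_body(rng: np.random.Generator, seq: bytes, spec: FixtureSpec,
               policy: str) -> bytes:
    """Sequence bytes → body lines, each terminated by a newline."""
    if not seq:
        return b""
    if policy == "unwrapped":
        lines = [seq]
    else:
        if policy == "uniform":
            widths = [spec.wrap_width] * ((len(seq) + spec.wrap_width - 1)
                                          // spec.wrap_width)
            # keep uniform wrapping truly uniform: trim the overshoot
            widths[-1] = len(seq) - spec.wrap_width * (len(widths) - 1)
        else:  # heterogeneous
            widths = _line_widths(rng, len(seq))
        lines = []
        pos = 0
        for w in widths:
            lines.append(seq[pos:pos + w])
            pos += w
    if spec.blank_line_prob > 0.0:
        with_blanks: list[bytes] = []
        for line in lines:
            with_blanks.append(line)
            if rng.random() < spec.blank_line_prob:
                with_blanks.append(b"")
        lines = with_blanks
    return b"".join(line + b"\n" for line in lines)


def generate(spec: FixtureSpec) -> tuple[bytes, list[FixtureRecord]]:
    """Serialize a synthetic multiFASTA and return it with its ground truth.

    Identical spec (seed included) → byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alphabet = ALPHABETS[spec.alphabet]
    chunks: list[bytes] = []
    records: list[FixtureRecord] = []
    for i in range(spec.n_records):
        seq_id = spec.ids[i] if spec.ids is not None else f"seq{i:05d}"
        empty = rng.random() < spec.empty_prob
        length = 0 if empty else int(rng.integers(spec.min_len, spec.max_len + 1))
        seq = _random_sequence(rng, length, alphabet, spec.gap_fraction)
        description = (f"synthetic record {i} len={length}"
                       if rng.random() < spec.description_prob else None)
        header = f">{seq_id}" + (f" {description}" if description else "")
        policy = spec.wrap
        if policy == "mixed":
            policy = ("unwrapped", "uniform", "heterogeneous")[int(rng.integers(3))]
        body = _wrap_body(rng, seq, spec, policy)
        chunks.append(header.encode() + b"\n" + body)
        records.append(FixtureRecord(seq_id, description, seq))
    data = b"".join(chunks)
    if not spec.trailing_newline and data.endswith(b"\n"):
        data = data[:-1]
    return data, records


def benchmark_spec(seed: int = 0) -> FixtureSpec:
    """~100 MiB preset: 10 000 mixed-wrapping records of ~10 kb each.

    A desk-scale stand-in for proteome-sized mounts; big enough that byte
    arithmetic bugs and accidental O(file) work per read would show, small
    enough to generate in seconds.
    """
    return FixtureSpec(
        seed=seed, n_records=10_000, min_len=8_000, max_len=12_000,
        wrap="mixed", wrap_width=60, gap_fraction=0.01,
        description_prob=0.3, empty_prob=0.001,
    )


def sweep_specs(n: int, base_seed: int = 0) -> list[FixtureSpec]:
    """``n`` format-diverse small specs cycling through every feature
    combination (wrapping, gaps, empties, blank lines, trailing newline)."""
    variants = [
        dict(wrap="uniform", wrap_width=10),
        dict(wrap="uniform", wrap_width=60, gap_fraction=0.3),
        dict(wrap="unwrapped"),
        dict(wrap="heterogeneous", blank_line_prob=0.1),
        dict(wrap="mixed", empty_prob=0.3),
        dict(wrap="uniform", wrap_width=5, trailing_newline=False),
        dict(wrap="heterogeneous", alphabet="protein"),
        dict(wrap="mixed", alphabet="any", gap_fraction=0.1,
             trailing_newline=False),
        dict(wrap="unwrapped", empty_prob=1.0),
    ]
    specs = []
    for i in range(n):
        v = variants[i % len(variants)]
        specs.append(replace(
            FixtureSpec(seed=base_seed + i, n_records=1 + i % 6, max_len=150),
            **v))
    return specs
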