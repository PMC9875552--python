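# Methods & design notes

## The model

`fastafs` treats one multiFASTA file as a database with a byte-exact index.
A single sequential scan produces, per record:

- the verbatim header (`raw` bytes, split into an ID — the maximal
  non-whitespace run after `>` — and an optional description);
- `header_start`, `seq_start`, `seq_end`: byte offsets such that the spans
  `[header_start, seq_end)`, concatenated in file order after the optional
  blank-line preamble, reproduce the input byte-for-byte. `seq_end` extends
  to the next header (or EOF), so internal blank lines and the terminal
  newline are attributed to the record they follow;
- a run-length-compressed line layout: `(count, width)` runs of per-line base
  counts, including zero-width runs for blank lines. A uniformly wrapped
  chromosome costs one or two runs regardless of length.

Base→byte arithmetic walks the runs: base *k* (1-based) of a record lies at
`seq_start + offset(k−1)` where each full line of width *w* costs `w + 1`
bytes (the newline) and each blank line costs 1. A 1-based closed interval
`START–END` therefore resolves to a byte span in time proportional to the
number of width changes, not to the sequence length; the span is read once
and its newlines removed.

Accepted inputs: UNIX newlines only (`\r` anywhere aborts the mount — the
tool refuses rather than guesses), every record must have an ID, and IDs must
be usable as filename components (no `/`, no NUL, no whitespace, not `.` or
`..`, ≤ 255 bytes). Sequence bytes are otherwise unconstrained: IUPAC or not,
alignment gaps, arbitrary printable characters, empty sequences, wrapped or
not, homogeneous padding or not. Duplicate IDs abort the mount: silently
suffixing them would corrupt downstream joins keyed on ID.

## Edit semantics

Mutations are staged as a write-back log and applied to an in-memory
*effective* record list, so every virtual file (including `labels.txt`,
`infos.csv` and `get/`) reflects edits immediately while the on-disk file
stays untouched until flush. Semantics of the four operations:

- **rename** swaps the ID token of the header, preserving the description
  and its separating whitespace verbatim; collisions are errors.
- **delete** removes the record from the effective list.
- **overwrite** replaces the body with the caller's bytes exactly as written
  (no re-wrapping; the record becomes "wrapped as written"). Payloads that
  contain a line starting with `>` or any `\r` are rejected up front — they
  would corrupt the FASTA on flush.
- **append** accepts only payloads carrying the FASTA signature (first line
  starting with `>`); anything else is ignored and logged, so stray files
  dropped into `append/` cannot damage the mount. Parsed records keep their
  payload's exact header and body bytes. Duplicate IDs (within the payload or
  against the mount) reject the whole payload atomically.

Edited and appended bodies gain a terminal newline when the payload lacks
one, so the following header always starts at column 0. The projected byte
offsets shown in `infos.csv` while edits are pending are the offsets the
records will occupy after flush; for an unedited mount they equal the on-disk
offsets (tested).

**Flush** renders the effective file into a temporary sibling
(`<file>.fastafs_tmp.<pid>`), fsyncs it and atomically `os.replace`s the
target: a crash or I/O failure mid-flush leaves the original intact.
Untouched records are copied as verbatim spans (8 MiB chunks), so formatting
is preserved and the no-edit flush is the identity. Flush happens on
`fsync`/`fsyncdir`, on unmount, or automatically when staging would push the
payload footprint past the cache budget (default 500 MiB, user-settable).
Full-rewrite-plus-rename was chosen over in-place splicing for crash safety
and simplicity; splicing is an optimization, not a semantic need. One
boundary case: a single staged payload larger than the entire budget is
flushed-around and then staged anyway — the footprint invariant is restored
at the next flush, and refusing the edit would lose user data.

The op log can be *compacted* (`EditSession.compacted_ops()`) into a minimal
delete/rename/overwrite/append list derived from the effective state, with
rename cycles broken through temporary IDs; equivalence with the uncompacted
log is property-tested. The flush path serializes from the effective state
directly, which is by construction the fully compacted behavior.

External modification of a mounted file voids all integrity guarantees; the
session records size+mtime at open and logs a warning if they changed by
flush time, but does not attempt reconciliation.

## The virtual tree

All filesystem semantics live in `FastaVfs`, a mount-independent
POSIX-shaped contract (getattr/listdir/read/write/create/unlink/rename/
truncate/fsync/release). The FUSE adapter is a zero-logic translation layer,
imported lazily so the library works (and is fully testable) on hosts
without a FUSE binding; callback dispatch is single-threaded because the edit
log is order-sensitive. Noteworthy choices:

- Node naming is `seqs/<ID>.seq` and `fasta/<ID>.fa`.
- Writes to `seqs/` and `append/` are buffered per open handle and applied on
  release: POSIX writes arrive in arbitrary chunks and a half-written record
  must never be observable. `append/` slot names are not retained.
- `get/` lists empty but serves any `ID:START-END` read; its node sizes are
  computed lazily (`END − START + 1`). Out-of-range or malformed regions
  surface as nonexistent files; reads never clamp, because silent truncation
  corrupts downstream coordinates.
- Region strings split at the last `:` whose suffix parses as two positive
  integers; when the candidate prefix set is checked against the index, the
  longest existing ID wins, so IDs containing `:` still resolve.
- `create()` is allowed only in `seqs/` (a new empty record — empty
  sequences are legal) and `append/` (a drop-box slot).
- Renaming a sequence file to a destination outside `seqs/` deletes the
  record from the mount, mirroring `mv` semantics out of the tree.

## Backends

`mmap` (default), `file` (seek & read) and `ram` (whole file cached) satisfy
one byte-level contract and are property-tested to return identical bytes
for every operation. The RAM backend refuses files larger than 80 % of
`MemAvailable` instead of thrashing. The write-back budget default of
500 MiB balances flush latency against staging memory.

## Synthetic data

The fixture generator (`fastafs.fixtures`) emulates the *formatting*
diversity the mount layer must tolerate — uniform/heterogeneous/absent
wrapping, blank lines inside records, alignment gaps, empty sequences,
missing trailing newline, DNA/protein/arbitrary alphabets, optional
descriptions — and returns the exact ground-truth triples used to build each
file, so tests carry an intrinsic oracle. Sequences are compositionally
random; the generator does not model biological content (codon structure,
repeats, realistic length distributions), so passing tests demonstrate
format-correctness and byte arithmetic, not biological plausibility — which
is the relevant claim for a filesystem layer. The benchmark preset (10 000
records of 8–12 kb, mixed wrapping, ~100 MiB) is a desk-scale stand-in for
proteome-sized mounts: large enough to expose accidental O(file) work per
read, small enough to generate in seconds. The acceptance script's scaled
benchmark performs 100 000 random subsequence reads against it.

## Numerical / boundary conventions

- Intervals are 1-based and closed; length `END − START + 1`.
- Reads at or past EOF return empty bytes (standard POSIX read contract).
- Sparse writes pad with NUL bytes, as a real filesystem would.
- Empty mounted files are legal (zero records), as are all-blank files.
- Header text round-trips through `surrogateescape`, so non-UTF-8 header
  bytes survive rename and relabeling untouched.

## Known limitations

- FASTQ, compressed input (gzip/bgzip), and `.fai` emission are out of scope;
  third-party index files become stale after edits and must be regenerated.
- No reverse-complement/strand-aware queries in `get/`.
- Single-writer model: concurrent external modification is undefined beyond
  the staleness warning; no journaling across process crashes (the edit log
  is memory-only until flush).
- Kernel mounting requires the optional FUSE binding and a FUSE-capable OS
  (Linux, macOS, BSD); Windows is unsupported.
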