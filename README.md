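# fastafs

**A multiFASTA file, mounted as a filesystem.**

Large multiFASTA files are awkward to edit: text editors choke on
multi-gigabyte inputs, and because headers and sequences interleave, stream
tools like `sed` or `awk` cannot operate on the sequences without a parsing
step. `fastafs` dissolves the problem by exposing one multiFASTA file as a
tree of virtual files, so every sequence can be read, sliced, edited, renamed,
deleted or appended with ordinary file operations — `cat`, `mv`, `rm`, `cp`,
your editor, or any program that opens files — while the tool keeps the
underlying multiFASTA consistent and format-preserving.

```
mountpoint/
├── labels.txt       all headers (ID + optional description), read-only
├── infos.txt        human-readable file & per-sequence summary, read-only
├── infos.csv        the same table as CSV, read-only
├── seqs/<ID>.seq    raw sequence bodies — read-write
├── fasta/<ID>.fa    single-record FASTA views — read-only
├── append/          drop-box: FASTA files written here are appended
└── get/             read ID:START-END for on-the-fly subsequences
```

The model underneath is a faidx-style index with byte-exact line-layout
metadata: for every record the byte offsets of its header and body plus the
run-length-compressed per-line base counts, so a 1-based closed interval
`ID:START-END` (length `END − START + 1`) maps to a byte span in O(#line-width
changes) without touching the rest of the file. Edits are a write-back log:
staged in memory (500 MiB budget by default), immediately visible in every
virtual file, and propagated on `fsync`/unmount — or automatically when the
budget would overflow — by atomically rewriting the file, copying untouched
records as verbatim byte spans. Wrapped, unwrapped, heterogeneously padded,
gapped and empty sequences all round-trip bit-exact.

Three interchangeable access backends serve reads: memory-mapped I/O
(default, fast repeated access through the page cache), plain seek-and-read
(smallest footprint), and whole-file RAM caching (fastest, costs file-sized
memory).

## Worked example

```python
from fastafs import EditSession, FastaVfs
from fastafs.fixtures import FixtureSpec, generate

spec = FixtureSpec(seed=0, n_records=3, min_len=30, max_len=40,
                   wrap="uniform", wrap_width=20, ids=("chr1", "chrMT", "chrX"))
data, _ = generate(spec)
open("toy.fa", "wb").write(data)

vfs = FastaVfs(EditSession("toy.fa"))
print(vfs.read("labels.txt").decode())
print(vfs.read("infos.csv").decode())
print(vfs.read("get/chr1:5-16").decode())
vfs.unlink("seqs/chrMT.seq")                   # rm seqs/chrMT.seq
vfs.rename("seqs/chr1.seq", "seqs/chr01.seq")  # mv seqs/chr1.seq ...
vfs.unmount()                                  # flushes the edit log
```

prints

```
chr1 synthetic record 0 len=35
chrMT
chrX

id,description,length,start_offset,end_offset
chr1,synthetic record 0 len=35,35,32,69
chrMT,,30,76,108
chrX,,35,114,151

AATGTGGTGGGG
```

`labels.txt` is the header register; `infos.csv` adds each sequence's base
count and the byte offsets of its body inside the mounted file (`chr1`'s 35
bases start at byte 32); `get/chr1:5-16` returns bases 5..16 inclusive —
twelve bases, closed interval. After `unmount()` the file on disk contains
only `chr01` (renamed in the header, sequence bytes untouched) and `chrX`,
with the original 20-column wrapping preserved:

```
>chr01 synthetic record 0 len=35
CCAAAATGTGGTGGGGTCTG
ACTGATGTAATAGAC
>chrX
GCGGCCGGGCTCCTCAGGAA
CTCTCATTAAGCGAT
```

## Extending

The `infos.csv` column set (`id,description,length,start_offset,end_offset`)
is deliberately minimal; `fastafs.views.sequence_rows()` is the single point
to extend if you need more per-sequence statistics. See `docs/methods.md`
for the data model, numerical conventions and known limitations.
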