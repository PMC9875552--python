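"""Staged mutations, the effective index, flushing and op-log compaction."""

from __future__ import annotations

import logging
import os
import random

import pytest

from fastafs.access import DEFAULT_CACHE_BYTES
from fastafs.edits import EditSession
from fastafs.errors import (
    AlreadyExists,
    DuplicateId,
    InvalidId,
    InvalidSequencePayload,
    NotFound,
    StorageError,
)
from fastafs.fixtures import FixtureSpec, generate, sweep_specs
from fastafs.model import Region, scan_multifasta

from conftest import apply_ops_naive, naive_parse


def session_on_disk(write_fasta, data: bytes, **kw) -> EditSession:
    return EditSession(write_fasta(data), **kw)


class TestRename:
    def test_prepend_chr_loop(self, write_fasta):
        """mv seqs/$i seqs/chr$i for every sequence: ids gain the prefix,
        every sequence byte survives identically."""
        data, _ = generate(FixtureSpec(seed=5, n_records=6, max_len=200,
                                       wrap="mixed", gap_fraction=0.1))
        s = session_on_disk(write_fasta, data)
        before = {i: s.raw(i) for i in s.ids()}
        for i in list(s.ids()):
            s.stage_rename(i, "chr" + i)
        assert s.ids() == ["chr" + i for i in before]
        s.flush()
        after = open(s.path, "rb").read()
        assert [i for i, _, _ in naive_parse(after)] == \
            ["chr" + i for i in before]
        for i, body in before.items():
            assert s.raw("chr" + i) == body

    def test_rename_to_self_is_noop(self):
        s = EditSession(data=b">a\nAC\n")
        s.stage_rename("a", "a")
        assert not s.dirty

    def test_rename_collision(self):
        s = EditSession(data=b">a\nAC\n>b\nGT\n")
        with pytest.raises(AlreadyExists):
            s.stage_rename("a", "b")

    def test_rename_validates_target_id(self):
        s = EditSession(data=b">a\nAC\n")
        with pytest.raises(InvalidId):
            s.stage_rename("a", "bad/id")

    def test_rename_unknown(self):
        with pytest.raises(NotFound):
            EditSession(data=b">a\nAC\n").stage_rename("z", "y")

    def test_rename_preserves_description_bytes(self, write_fasta):
        s = session_on_disk(write_fasta, b">a  two  spaces\nAC\n")
        s.stage_rename("a", "longer_name")
        s.flush()
        assert open(s.path, "rb").read() == b">longer_name  two  spaces\nAC\n"

    def test_flush_after_rename_touches_only_the_id_token(self, write_fasta):
        data, _ = generate(FixtureSpec(seed=9, n_records=4, max_len=300,
                                       wrap="heterogeneous", blank_line_prob=0.2))
        s = session_on_disk(write_fasta, data)
        victim = s.ids()[2]
        s.stage_rename(victim, "renamed")
        s.flush()
        assert open(s.path, "rb").read() == apply_ops_naive(
            data, [("rename", victim, "renamed")])


class TestDeleteOverwrite:
    def test_delete_removes_from_all_views(self, write_fasta):
        data, _ = generate(FixtureSpec(
            seed=2, n_records=4, min_len=5, max_len=60,
            ids=("chr1", "chr2", "chrMT", "chrX")))
        s = session_on_disk(write_fasta, data)
        s.stage_delete("chrMT")
        assert "chrMT" not in s.ids()
        with pytest.raises(NotFound):
            s.raw("chrMT")
        s.flush()
        assert open(s.path, "rb").read() == apply_ops_naive(
            data, [("delete", "chrMT")])

    def test_delete_unknown(self):
        with pytest.raises(NotFound):
            EditSession(data=b">a\nAC\n").stage_delete("z")

    def test_overwrite_visible_immediately(self):
        s = EditSession(data=b">a\nACGT\n>b\nAC\n")
        s.stage_overwrite("a", b"GGGG\n")
        assert s.fasta("a") == b">a\nGGGG\n"
        assert s.length("a") == 4
        assert s.subsequence("a", Region("a", 2, 3)) == b"GG"

    def test_overwrite_identical_bytes_roundtrips(self, write_fasta):
        data = b">a\nAC\nGT\n>b\nTT\n"
        s = session_on_disk(write_fasta, data)
        s.stage_overwrite("a", b"AC\nGT\n")
        s.flush()
        assert open(s.path, "rb").read() == data

    @pytest.mark.parametrize("payload", [b"AC\n>evil\n", b">evil\n", b"AC\rGT\n"])
    def test_overwrite_rejects_corrupting_payload(self, payload):
        s = EditSession(data=b">a\nAC\n")
        with pytest.raises(InvalidSequencePayload):
            s.stage_overwrite("a", payload)
        assert not s.dirty

    def test_overwrite_gets_terminal_newline(self, write_fasta):
        s = session_on_disk(write_fasta, b">a\nAC\n>b\nGT\n")
        s.stage_overwrite("a", b"TT")
        s.flush()
        assert open(s.path, "rb").read() == b">a\nTT\n>b\nGT\n"

    def test_overwrite_to_empty(self, write_fasta):
        s = session_on_disk(write_fasta, b">a\nAC\n>b\nGT\n")
        s.stage_overwrite("a", b"")
        assert s.length("a") == 0
        s.flush()
        assert open(s.path, "rb").read() == b">a\n>b\nGT\n"


class TestAppend:
    def test_append_fasta_payload(self, write_fasta):
        data = b">a\nAC\n"
        payload = b">x\nTTTT\n>y desc\nGG\nGG\n"
        s = session_on_disk(write_fasta, data)
        assert s.stage_append(payload) == 2
        assert s.ids() == ["a", "x", "y"]
        s.flush()
        assert open(s.path, "rb").read() == apply_ops_naive(
            data, [("append", payload)])

    def test_append_after_unterminated_last_record(self, write_fasta):
        s = session_on_disk(write_fasta, b">a\nAC")  # no trailing newline
        s.stage_append(b">b\nGT\n")
        s.flush()
        assert open(s.path, "rb").read() == b">a\nAC\n>b\nGT\n"

    def test_non_fasta_payload_ignored_with_log(self, caplog):
        s = EditSession(data=b">a\nAC\n")
        with caplog.at_level(logging.WARNING, logger="fastafs.edits"):
            assert s.stage_append(b"hello world\n") == 0
        assert s.ids() == ["a"] and not s.dirty
        assert len(caplog.records) == 1

    def test_empty_payload_ignored(self):
        s = EditSession(data=b">a\nAC\n")
        assert s.stage_append(b"") == 0
        assert not s.dirty

    def test_duplicate_ids_rejected_atomically(self):
        s = EditSession(data=b">a\nAC\n")
        with pytest.raises(DuplicateId):
            s.stage_append(b">b\nGG\n>a\nTT\n")
        assert s.ids() == ["a"] and not s.dirty
        with pytest.raises(DuplicateId):
            s.stage_append(b">c\nGG\n>c\nTT\n")
        assert s.ids() == ["a"]

    def test_append_payload_without_trailing_newline(self, write_fasta):
        s = session_on_disk(write_fasta, b">a\nAC\n")
        s.stage_append(b">b\nGT")
        s.flush()
        assert open(s.path, "rb").read() == b">a\nAC\n>b\nGT\n"

    def test_append_conserves_counts_and_bases(self):
        s = EditSession(data=b">a\nACGT\n")
        total_before = sum(s.length(i) for i in s.ids())
        s.stage_append(b">b\nAC\n>c\nGTGT\n")
        assert len(s.ids()) == 3
        assert sum(s.length(i) for i in s.ids()) == total_before + 6


class TestFlush:
    def test_no_edit_flush_is_byte_identical(self, write_fasta):
        for spec in sweep_specs(12, base_seed=100):
            data, _ = generate(spec)
            s = session_on_disk(write_fasta, data)
            s.flush()
            assert open(s.path, "rb").read() == data
            s.close()

    def test_flush_is_idempotent(self, write_fasta):
        s = session_on_disk(write_fasta, b">a\nAC\n>b\nGT\n")
        s.stage_delete("b")
        s.flush()
        first = open(s.path, "rb").read()
        s.flush()
        assert open(s.path, "rb").read() == first == b">a\nAC\n"

    def test_mixed_ops_match_naive_oracle(self, write_fasta):
        data, _ = generate(FixtureSpec(seed=13, n_records=5, min_len=3,
                                       max_len=120, wrap="mixed",
                                       gap_fraction=0.1))
        ids = scan_multifasta(data).ids()
        s = session_on_disk(write_fasta, data)
        payload = b">new1\nTTTT\n>new2\nGG\n"
        s.stage_rename(ids[0], "zeta")
        s.stage_delete(ids[2])
        s.stage_overwrite(ids[1], b"CCCC\n")
        s.stage_append(payload)
        s.flush()
        assert open(s.path, "rb").read() == apply_ops_naive(data, [
            ("rename", ids[0], "zeta"),
            ("delete", ids[2]),
            ("overwrite", ids[1], b"CCCC\n"),
            ("append", payload),
        ])

    def test_failed_flush_leaves_original_intact(self, write_fasta, monkeypatch):
        data = b">a\nAC\n>b\nGT\n"
        s = session_on_disk(write_fasta, data)
        s.stage_delete("b")

        def boom(src, dst):
            raise OSError("disk full")

        monkeypatch.setattr(os, "replace", boom)
        with pytest.raises(StorageError):
            s.flush()
        monkeypatch.undo()
        assert open(s.path, "rb").read() == data
        assert not [p for p in os.listdir(os.path.dirname(s.path))
                    if ".fastafs_tmp." in p]

    def test_in_memory_session_flush(self):
        s = EditSession(data=b">a\nAC\n>b\nGT\n")
        s.stage_delete("a")
        s.flush()
        assert s.render() == b">b\nGT\n"
        assert s.index.ids() == ["b"]

    def test_staleness_warning_on_external_modification(self, write_fasta, caplog):
        s = session_on_disk(write_fasta, b">a\nAC\n")
        with open(s.path, "ab") as fh:  # external writer breaks guarantees
            fh.write(b">b\nGT\n")
        os.utime(s.path, ns=(1, 1))
        with caplog.at_level(logging.WARNING, logger="fastafs.edits"):
            s.flush()
        assert any("changed on disk" in r.message for r in caplog.records)


class TestBudget:
    def test_default_budget_is_500_mib(self):
        assert DEFAULT_CACHE_BYTES == 500 * 2 ** 20
        assert EditSession(data=b"").budget_bytes == DEFAULT_CACHE_BYTES

    def test_empty_footprint_is_zero(self):
        assert EditSession(data=b">a\nAC\n").memory_footprint() == 0

    def test_staging_past_budget_flushes_first(self, write_fasta):
        s = session_on_disk(write_fasta, b">a\nAC\n", budget_bytes=64)
        s.stage_overwrite("a", b"G" * 100 + b"\n")
        assert s.flush_count == 1 and s.autoflush_count == 1
        assert s.dirty  # the oversized op itself is staged, not lost
        s.flush()
        assert open(s.path, "rb").read() == b">a\n" + b"G" * 100 + b"\n"

    def test_budgeted_end_state_equals_unbudgeted(self, write_fasta):
        data, _ = generate(FixtureSpec(seed=17, n_records=4, min_len=5,
                                       max_len=50))
        ids = scan_multifasta(data).ids()
        ops = [("overwrite", ids[0], b"A" * 40 + b"\n"),
               ("overwrite", ids[1], b"C" * 40 + b"\n"),
               ("append", b">zz\n" + b"T" * 40 + b"\n")]
        outputs = []
        for budget in (60, DEFAULT_CACHE_BYTES):
            s = session_on_disk(write_fasta, data, budget_bytes=budget)
            for op in ops:
                if op[0] == "overwrite":
                    s.stage_overwrite(op[1], op[2])
                else:
                    s.stage_append(op[1])
            s.flush()
            outputs.append(open(s.path, "rb").read())
        assert outputs[0] == outputs[1] == apply_ops_naive(data, ops)


class TestEffectiveIndexAndCompaction:
    def _random_ops(self, s: EditSession, rng: random.Random, n_ops: int):
        for k in range(n_ops):
            ids = s.ids()
            choice = rng.randrange(4)
            if choice == 0 and ids:
                s.stage_rename(rng.choice(ids), f"rn{rng.randrange(10**6)}")
            elif choice == 1 and len(ids) > 1:
                s.stage_delete(rng.choice(ids))
            elif choice == 2 and ids:
                body = bytes(rng.choice(b"ACGT-")
                             for _ in range(rng.randrange(0, 30)))
                s.stage_overwrite(rng.choice(ids), body)
            else:
                s.stage_append(
                    f">ap{rng.randrange(10**6)}\nACGTAC\n".encode())

    @pytest.mark.parametrize("seed", range(25))
    def test_effective_index_equals_flush_and_rescan(self, seed, write_fasta):
        """After a random op sequence the live effective index matches the
        index obtained by flushing and rescanning the file."""
        rng = random.Random(seed)
        spec = random.Random(seed + 1000).choice(sweep_specs(9, base_seed=seed))
        data, _ = generate(spec)
        s = session_on_disk(write_fasta, data)
        self._random_ops(s, rng, rng.randrange(1, 12))
        eff = s.effective_index()
        expected_render = s.render()
        fresh = scan_multifasta(expected_render)
        assert eff.ids() == fresh.ids()
        assert [e.length_bases for e in eff] == \
            [e.length_bases for e in fresh]
        assert [(e.seq_start, e.seq_end) for e in eff] == \
            [(e.seq_start, e.seq_end) for e in fresh]
        s.flush()
        assert open(s.path, "rb").read() == expected_render

    @pytest.mark.parametrize("seed", range(15))
    def test_compacted_ops_equal_uncompacted(self, seed, write_fasta):
        rng = random.Random(10_000 + seed)
        data, _ = generate(FixtureSpec(seed=seed, n_records=5, min_len=2,
                                       max_len=60, wrap="mixed"))
        s = session_on_disk(write_fasta, data)
        self._random_ops(s, rng, rng.randrange(2, 10))
        compacted = s.compacted_ops()
        assert len(compacted) <= max(len(s.ops), 1)
        replay = EditSession(data=data)
        replay.apply_ops(compacted)
        assert replay.render() == s.render()

    def test_compaction_handles_rename_swap(self):
        s = EditSession(data=b">a\nAC\n>b\nGT\n")
        s.stage_rename("a", "tmp_hold")
        s.stage_rename("b", "a")
        s.stage_rename("tmp_hold", "b")
        replay = EditSession(data=b">a\nAC\n>b\nGT\n")
        replay.apply_ops(s.compacted_ops())
        assert replay.render() == s.render() == b">b\nAC\n>a\nGT\n"
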