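"""Reference packing, group index, alignment search and record coding."""

import random

import pytest

from fqzlite.refmap import (
    AlignmentRecord, align_read, build_index, code_alignments,
    decode_alignments, matched_positions, pack_reference,
    simulate_index_discard, unpack_reference,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(s):
    return "".join(_COMP[c] for c in reversed(s))


@pytest.fixture(scope="module")
def genome_index():
    rng = random.Random(99)
    genome = "".join(rng.choice("ACGT") for _ in range(60_000))
    packed, idx = build_index(genome, table_bits=17)
    return genome, packed, idx


class TestPackedReference:
    def test_roundtrip(self):
        seq = "ACGTACGTTGCA"
        assert unpack_reference(pack_reference(seq)) == seq

    def test_n_runs_are_deleted_but_recorded(self):
        seq = "ACGTNNNNACGTN"
        pr = pack_reference(seq)
        assert pr.length == 8
        assert pr.n_map == [(4, 4), (8, 1)]
        assert unpack_reference(pr, with_n=True) == seq

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            pack_reference("ACGX")


class TestIndex:
    def test_random_genome_low_load_discards_under_1_percent(self, genome_index):
        _, _, idx = genome_index
        assert idx.discard_fraction < 0.01

    def test_reference_shorter_than_a_group_gives_empty_index(self):
        packed, idx = build_index("ACGTACGT", table_bits=10)
        assert idx.n_groups == 0
        rec = align_read("ACGT" * 10, idx, packed)
        assert rec.unmatched

    def test_stored_checksums_verify(self, genome_index):
        from fqzlite.refmap import GROUP, _group_hash
        _, packed, idx = genome_index
        used = (idx.pointers > 0).sum()
        assert used == idx.n_groups - idx.n_discarded
        checked = 0
        for slot in range(0, 1 << idx.table_bits, 97):
            ptr = int(idx.pointers[slot])
            if ptr == 0:
                continue
            g = ptr - 1
            h = _group_hash(packed.codes[g * GROUP:(g + 1) * GROUP])
            assert int(idx.checksums[slot]) == (h >> idx.table_bits) & 31
            checked += 1
        assert checked > 10


class TestAlignRead:
    def test_verbatim_read_matches_perfectly(self, genome_index):
        genome, packed, idx = genome_index
        rec = align_read(genome[1234:1334], idx, packed)
        assert not rec.unmatched
        assert rec.m == (101, 101, 101, 101)
        assert rec.dir == 0 and rec.ptr == 1234

    def test_revcomp_with_one_substitution(self, genome_index):
        genome, packed, idx = genome_index
        win = genome[7000:7100]
        read = _revcomp(win)
        read = read[:61] + _COMP[read[61]] + read[62:]
        rec = align_read(read, idx, packed)
        assert not rec.unmatched and rec.dir == 1
        assert rec.ptr == 7000
        # in match orientation the substitution sits at (100 - 61) 1-based
        assert rec.m[0] == 100 - 61 and rec.m[1:] == (101, 101, 101)

    def test_heavily_mutated_first_half_is_unmatched(self, genome_index):
        genome, packed, idx = genome_index
        w = list(genome[9000:9100])
        for p in (2, 11, 21, 33, 44):
            w[p] = _COMP[w[p]]
        assert align_read("".join(w), idx, packed).unmatched

    def test_reads_shorter_than_a_group_are_unmatched(self, genome_index):
        _, packed, idx = genome_index
        assert align_read("ACGTACGT", idx, packed).unmatched

    def test_best_window_agrees_with_brute_force(self, genome_index):
        # mutated reads can only be found when at least one 32-base read
        # window aligned to a reference group boundary stays clean, so an
        # occasional unmatched read is legitimate; every *matched* record
        # must agree with a brute-force mismatch scan of its window
        genome, packed, idx = genome_index
        rng = random.Random(5)
        matched = 0
        for _ in range(25):
            p = rng.randrange(0, len(genome) - 100)
            w = list(genome[p:p + 100])
            for _ in range(rng.randrange(0, 3)):
                q = rng.randrange(100)
                w[q] = _COMP[w[q]]
            read = "".join(w)
            rec = align_read(read, idx, packed)
            if rec.unmatched:
                # only acceptable when every group-aligned window of the
                # read (either strand) contains a mutation
                offset = (-p) % 32
                dirty = any(read[j:j + 32] != genome[p + j:p + j + 32]
                            for j in range(offset, 69, 32))
                assert dirty
                continue
            matched += 1
            window = genome[rec.ptr:rec.ptr + 100]
            cand = read if rec.dir == 0 else _revcomp(read)
            mm = [i + 1 for i, (a, b) in enumerate(zip(cand, window)) if a != b]
            expect = tuple((mm + [101] * 4)[:4]) if len(mm) <= 4 else \
                tuple(mm[:4])
            assert rec.m == expect
        assert matched >= 20


class TestRecordCoding:
    def test_all_unmatched_fast_mode_is_one_byte_each(self):
        recs = [AlignmentRecord(True, read_len=50) for _ in range(20)]
        assert len(code_alignments(recs, slow=False)) == 20

    @pytest.mark.parametrize("slow", [False, True])
    def test_roundtrip_fuzz(self, slow, rng):
        recs = []
        for _ in range(100):
            if rng.random() < 0.3:
                recs.append(AlignmentRecord(True, read_len=70))
            else:
                m = sorted(rng.sample(range(1, 71), 3)) + [71]
                recs.append(AlignmentRecord(
                    False, tuple(m), rng.randrange(2),
                    rng.randrange(1 << 20), 70))
        data = code_alignments(recs, slow)
        back = decode_alignments(data, [70] * len(recs), slow)
        for a, b in zip(recs, back):
            assert a.unmatched == b.unmatched
            if not a.unmatched:
                assert (tuple(a.m), a.dir, a.ptr) == (tuple(b.m), b.dir, b.ptr)

    def test_sorted_pointers_compress_better_in_slow_mode(self):
        recs = [AlignmentRecord(False, (101, 101, 101, 101), 0, 1000 + 37 * i, 100)
                for i in range(300)]
        fast = code_alignments(recs, slow=False)
        slow = code_alignments(recs, slow=True)
        assert len(slow) <= len(fast) * 0.7

    def test_matched_positions_excludes_mismatches_and_tail(self):
        rec = AlignmentRecord(False, (10, 20, 101, 101), 0, 0, 100)
        pos = matched_positions(rec)
        assert 9 not in pos and 19 not in pos and len(pos) == 98
        rec = AlignmentRecord(False, (10, 20, 30, 60), 0, 0, 100)
        pos = matched_positions(rec)
        # literal tail from the fourth mismatch onward
        assert max(pos) == 58 and {9, 19, 29}.isdisjoint(pos)


def test_probe8_discard_grows_with_load():
    lo = simulate_index_discard(0.3, 16, seed=1)
    hi = simulate_index_discard(0.95, 16, seed=1)
    assert lo < 0.01 < hi
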