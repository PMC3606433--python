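"""Base packing, order-k models, model selection and the fastqz stack."""

import pytest
from hypothesis import given, settings, strategies as st

from fqzlite.coder import DirectContextModel, RangeEncoder
from fqzlite.seq_codec import (
    FastqzSeqDecoder, FastqzSeqEncoder, SeqModelConfig, group_sizes,
    pack_bases, select_model, seq_decode, seq_encode, unpack_bases,
)


class TestPacking:
    def test_tgga_packs_to_209(self):
        assert list(pack_bases("TGGA").data) == [209]

    def test_ccg_packs_to_64_as_three_bases(self):
        assert list(pack_bases("CCG").data) == [64]

    def test_g_start_takes_three_bases(self):
        pb = pack_bases("GAAA")
        assert group_sizes(pb.data)[0] == 3

    @given(st.text(alphabet="ACGT", max_size=50))
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_roundtrip_property(self, s):
        assert unpack_bases(pack_bases(s)) == s

    def test_full_group_bytes_stay_at_or_above_63(self, rng):
        for _ in range(200):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randrange(4, 30)))
            data = pack_bases(s).data
            assert all(v >= 63 for v in data[:-1])


def _parse_groups(seq):
    pb = pack_bases(seq)
    out, i = [], 0
    for g in group_sizes(pb.data):
        out.append(seq[i:i + g])
        i += g
    return out


class TestSelfSynchronization:
    READ = "TGGAATCAGATGGAATCATCGAATGGACTGGAATGGAATCA"

    def test_full_read_parses_as_published(self):
        assert _parse_groups(self.READ) == (
            "TGGA ATCA GAT GGA ATCA TCGA ATGG ACTG GAA TGGA ATCA".split())

    def test_shift1_and_shift3_parses_match_published_groupings(self):
        assert _parse_groups(self.READ[1:]) == (
            "GGA ATCA GAT GGA ATCA TCGA ATGG ACTG GAA TGGA ATCA".split())
        assert _parse_groups(self.READ[3:]) == (
            "AATC AGAT GGA ATCA TCGA ATGG ACTG GAA TGGA ATCA".split())

    def test_shifted_parses_converge_to_the_same_boundaries(self):
        # boundaries (absolute positions) of the unshifted parse
        def boundaries(shift):
            pos, bset = shift, set()
            for g in group_sizes(pack_bases(self.READ[shift:]).data):
                pos += g
                bset.add(pos)
            return bset
        b0 = boundaries(0)
        for shift in (1, 3):
            assert boundaries(shift) >= b0 & boundaries(shift)
            # convergence: identical boundaries from position 14 on
            assert {b for b in b0 if b >= 14} <= boundaries(shift)


class TestOrderK:
    def test_single_read_roundtrip(self):
        cfg = SeqModelConfig(k=4)
        data = seq_encode(["ACGT"], cfg)
        assert seq_decode(data, [4], SeqModelConfig(k=4)) == ["ACGT"]

    def test_iid_uniform_reads_cost_about_two_bits(self, rng):
        reads = ["".join(rng.choice("ACGT") for _ in range(100))
                 for _ in range(150)]
        data = seq_encode(reads, SeqModelConfig(k=8))
        bpb = len(data) * 8 / 15000
        assert 1.95 <= bpb <= 2.1

    def test_deep_coverage_learns_the_genome(self, rng):
        genome = "".join(rng.choice("ACGT") for _ in range(20_000))
        reads = []
        for _ in range(3000):       # 15x coverage
            p = rng.randrange(0, len(genome) - 100)
            reads.append(genome[p:p + 100])
        cfg = SeqModelConfig(k=12)
        data = seq_encode(reads, cfg)
        assert len(data) * 8 / 300_000 < 0.8
        assert seq_decode(data, [100] * 3000, SeqModelConfig(k=12)) == reads

    def test_small_genome_compresses_better_than_large(self, rng):
        def bpb(glen, n):
            genome = "".join(rng.choice("ACGT") for _ in range(glen))
            reads = []
            for _ in range(n):
                p = rng.randrange(0, glen - 100)
                reads.append(genome[p:p + 100])
            data = seq_encode(reads, SeqModelConfig(k=12))
            return len(data) * 8 / (100 * n)
        small = bpb(5_000, 1500)       # 30x of 5 kb
        large = bpb(150_000, 1500)     # ~1x of 150 kb: model stays cold
        assert small < large

    @pytest.mark.parametrize("cfg", [
        SeqModelConfig(k=6, use_revcomp=True),
        SeqModelConfig(k=6, dual_order7=True),
        SeqModelConfig(k=16, hashed=True, hash_bits=18),
    ])
    def test_variant_configs_roundtrip(self, cfg, rng):
        reads = ["".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 80)))
                 for _ in range(150)]
        data = seq_encode(reads, cfg)
        back = seq_decode(data, [len(r) for r in reads],
                          SeqModelConfig(**cfg.__dict__))
        assert back == reads

    def test_n_is_coded_as_symbol_zero(self):
        data = seq_encode(["ANGT"], SeqModelConfig(k=4))
        assert seq_decode(data, [4], SeqModelConfig(k=4)) == ["AAGT"]

    def test_revcomp_update_helps_on_two_strand_sampling(self, clean_sim):
        _, _, reads = clean_sim
        seqs = [s for _, s, _ in reads.fastq]
        plain = seq_encode(seqs, SeqModelConfig(k=12))
        rc = seq_encode(seqs, SeqModelConfig(k=12, use_revcomp=True))
        assert len(rc) <= len(plain) * 1.01


class TestSelectModel:
    def test_stronger_bias_wins(self):
        assert select_model([.97, .01, .01, .01], [.4, .3, .2, .1]) == 0
        assert select_model([.4, .3, .2, .1], [.97, .01, .01, .01]) == 1

    def test_tie_prefers_order_k(self):
        assert select_model([.25] * 4, [.25] * 4) == 0


class TestFastqzStack:
    def test_empty_input_is_header_only(self):
        enc = FastqzSeqEncoder(slow=True)
        assert len(enc.finish()) <= 8

    def test_roundtrip(self, rng):
        genome = "".join(rng.choice("ACGT") for _ in range(5000))
        reads = []
        for _ in range(200):
            p = rng.randrange(0, len(genome) - 80)
            reads.append(genome[p:p + 80])
        for slow in (False, True):
            enc = FastqzSeqEncoder(slow)
            for r in reads:
                enc.add(r)
            data = enc.finish()
            dec = FastqzSeqDecoder(data, slow)
            assert [dec.get(80) for _ in reads] == reads

    def test_stack_beats_order2_on_redundant_reads(self, rng):
        genome = "".join(rng.choice("ACGT") for _ in range(3000))
        reads = []
        for _ in range(300):        # 30x coverage: repeats dominate
            p = rng.randrange(0, len(genome) - 100)
            reads.append(genome[p:p + 100])
        packed = b"".join(pack_bases(r).data for r in reads)
        enc = FastqzSeqEncoder(slow=True)
        for r in reads:
            enc.add(r)
        stacked = enc.finish()
        rc = RangeEncoder()
        m = DirectContextModel(256)
        h = 0
        for b in packed:
            m.encode(rc, h, b)
            h = ((h << 8) | b) & 0xFFFF
        order2 = rc.flush()
        assert len(stacked) <= len(order2) * 0.8
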