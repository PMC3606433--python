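"""Container format, FASTQ round trips, corruption handling, accounting."""

import os

import pytest

from fqzlite import container_io as cio
from fqzlite.simdata import write_fastq

# the worked two-record FASTQ block (SRR062634 training-set excerpt)
REC1_ID = "@SRR062634.2724179 HWI-EAS110_103327062:6:13:11133:13696/1"
REC1_SEQ = "TGGAATCAGATGGAATCATCGAATGGACTGGAATGGAATCATTGAATGGACTCGAAAGG"
REC1_QUAL = "GGGFGGFDGGGGGGFGFGGGGGGGGGGGGGGEFGGGGFGEDGGGFGGGFEDFGCDFDG?"
REC2_ID = "@SRR062634.2724180 HWI-EAS110_103327062:6:13:11133:11572/1"
REC2_SEQ = "ATATAGTCCATTGTACTCCCTTGCTTAAATCTGGATCCCTGCAAATAAAAACATCTTCC"
REC2_QUAL = "GGGGGGGGFGGGGEGGFGGGEGGFDGEAEGGEEEEBEEEEEEEEEEEEEEEEEEECCCC"


def _write(tmp_path, records, plus_id=False, name="in.fastq"):
    path = tmp_path / name
    write_fastq(str(path), records, plus_id)
    return str(path)


@pytest.fixture(scope="module")
def sim_fastq(tmp_path_factory, small_sim):
    _, genome, reads = small_sim
    d = tmp_path_factory.mktemp("fq")
    path = d / "sim.fastq"
    write_fastq(str(path), reads.fastq)
    ref = d / "ref.fa"
    from fqzlite.simdata import write_fasta
    write_fasta(str(ref), genome)
    return str(path), str(ref)


class TestRoundTrips:
    def test_two_record_example_roundtrips_byte_exactly(self, tmp_path):
        records = [(REC1_ID, REC1_SEQ, REC1_QUAL),
                   (REC2_ID, REC2_SEQ, REC2_QUAL)]
        assert len(REC1_SEQ) == len(REC1_QUAL) == 59
        src = _write(tmp_path, records)
        for mode in ("store", "fqz", "fastqz"):
            out = str(tmp_path / f"out-{mode}.fastq")
            cio.compress_fastq(src, str(tmp_path / "c"), mode, "fast")
            cio.decompress(str(tmp_path / "c"), out)
            assert open(out, "rb").read() == open(src, "rb").read()

    def test_empty_fastq(self, tmp_path):
        src = _write(tmp_path, [])
        cio.compress_fastq(src, str(tmp_path / "c"), "fqz", "fast")
        cio.decompress(str(tmp_path / "c"), str(tmp_path / "o"))
        assert open(tmp_path / "o").read() == ""

    @pytest.mark.parametrize("mode,level", [
        ("fqz", "fast"), ("fqz", "medium"), ("fastqz", "fast")])
    def test_simulated_file_roundtrips(self, sim_fastq, tmp_path, mode, level):
        src, _ = sim_fastq
        cont = str(tmp_path / "c")
        cio.compress_fastq(src, cont, mode, level)
        cio.decompress(cont, str(tmp_path / "o"))
        assert open(tmp_path / "o", "rb").read() == open(src, "rb").read()

    def test_reference_mode_roundtrips(self, sim_fastq, tmp_path):
        src, ref = sim_fastq
        cont = str(tmp_path / "c")
        cio.compress_fastq(src, cont, "fastqz", "fast", reference=ref)
        cio.decompress(cont, str(tmp_path / "o"), reference=ref)
        assert open(tmp_path / "o", "rb").read() == open(src, "rb").read()

    def test_plus_line_dialect_preserved(self, tmp_path):
        records = [(REC1_ID, REC1_SEQ, REC1_QUAL)]
        src = _write(tmp_path, records, plus_id=True)
        cio.compress_fastq(src, str(tmp_path / "c"), "fqz", "fast")
        cio.decompress(str(tmp_path / "c"), str(tmp_path / "o"))
        assert open(tmp_path / "o", "rb").read() == open(src, "rb").read()

    def test_n_quality_convention_violations_still_roundtrip(self, tmp_path):
        # N with a non-zero quality and a non-N base with quality 0
        records = [("@weird", "ANGT", "I!I!"), ("@x", "NNNN", "IIII")]
        src = _write(tmp_path, records)
        cio.compress_fastq(src, str(tmp_path / "c"), "fqz", "medium")
        cio.decompress(str(tmp_path / "c"), str(tmp_path / "o"))
        assert open(tmp_path / "o", "rb").read() == open(src, "rb").read()


class TestErrors:
    def test_malformed_record_reports_index(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@ok\nACGT\n+\nIIII\n@bad\nACGT\n+\nIII\n")
        with pytest.raises(cio.ContainerError, match="record 1"):
            cio.compress_fastq(str(p), None, "fqz", "fast")

    def test_quality_out_of_phred_range_rejected(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@a\nACGT\n+\nII\x1fI\n")
        with pytest.raises(cio.ContainerError, match="Phred"):
            cio.compress_fastq(str(p), None, "fqz", "fast")

    def test_flipped_payload_bit_is_detected(self, sim_fastq, tmp_path):
        src, _ = sim_fastq
        cont = tmp_path / "c"
        cio.compress_fastq(src, str(cont), "fqz", "fast")
        data = bytearray(cont.read_bytes())
        data[len(data) // 2] ^= 0x10
        with pytest.raises(cio.ContainerError, match="checksum"):
            cio.decompress(bytes(data), str(tmp_path / "o"))

    def test_wrong_reference_is_refused(self, sim_fastq, tmp_path):
        src, ref = sim_fastq
        cont = str(tmp_path / "c")
        cio.compress_fastq(src, cont, "fastqz", "fast", reference=ref)
        with pytest.raises(cio.ContainerError, match="reference"):
            cio.decompress(cont, str(tmp_path / "o"), reference="ACGT" * 100)
        with pytest.raises(cio.ContainerError, match="reference"):
            cio.decompress(cont, str(tmp_path / "o"))

    def test_bad_magic_rejected(self):
        with pytest.raises(cio.ContainerError, match="magic"):
            cio.decompress(b"NOPE" + b"\x00" * 32)


class TestLossy:
    def test_lossy_q2_differs_only_in_quality_within_bound(self, sim_fastq,
                                                           tmp_path):
        src, _ = sim_fastq
        cont = str(tmp_path / "c")
        cio.compress_fastq(src, cont, "fqz", "medium", lossy_q=2)
        cio.decompress(cont, str(tmp_path / "o"))
        orig = open(src).read().split("\n")
        got = open(tmp_path / "o").read().split("\n")
        assert len(orig) == len(got)
        for i, (a, b) in enumerate(zip(orig, got)):
            if i % 4 == 3:
                for ca, cb in zip(a, b):
                    qa, qb = ord(ca) - 33, ord(cb) - 33
                    assert abs(qa - qb) <= 2 or (qa == 0 or qb == 0)
            else:
                assert a == b

    def test_size_is_monotone_in_q(self, sim_fastq, tmp_path):
        src, _ = sim_fastq
        sizes = {}
        for Q in (1, 2, 4):
            cont = str(tmp_path / f"c{Q}")
            cio.compress_fastq(src, cont, "fqz", "medium", lossy_q=Q)
            sizes[Q] = cio.stats(cont).sizes["Q"]
        assert sizes[4] <= sizes[2] <= sizes[1]


class TestStats:
    def test_store_mode_is_exactly_8_bits_per_base_and_quality(
            self, sim_fastq, tmp_path):
        src, _ = sim_fastq
        cont = str(tmp_path / "c")
        cio.compress_fastq(src, cont, "store", "fast")
        bd = cio.stats(cont)
        assert bd.bits_per_base == 8.0
        assert bd.bits_per_quality == 8.0

    def test_block_sizes_account_for_the_whole_file(self, sim_fastq, tmp_path):
        src, _ = sim_fastq
        cont = tmp_path / "c"
        cio.compress_fastq(src, str(cont), "fqz", "fast")
        bd = cio.stats(str(cont))
        total = cont.stat().st_size
        payload = sum(bd.sizes.values())
        # header + per-block framing (13 bytes each) + META block
        overhead = total - payload
        assert 0 < overhead < 2048
        assert bd.compressed_size == total

    def test_reference_reduces_bits_per_base(self, sim_fastq, tmp_path):
        src, ref = sim_fastq
        a = cio.compress_fastq(src, str(tmp_path / "a"), "fastqz", "fast")
        b = cio.compress_fastq(src, str(tmp_path / "b"), "fastqz", "fast",
                               reference=ref)
        assert b.bits_per_base < a.bits_per_base

    def test_medium_mode_lands_in_the_expected_ratio_regime(
            self, sim_fastq, tmp_path):
        src, _ = sim_fastq
        bd = cio.compress_fastq(src, str(tmp_path / "c"), "fqz", "medium")
        assert bd.overall_ratio < 0.33


def test_cli_compress_decompress_stats(tmp_path, sim_fastq):
    from click.testing import CliRunner
    from fqzlite.cli import main
    src, _ = sim_fastq
    cont = str(tmp_path / "c.fqz")
    out = str(tmp_path / "o.fastq")
    r = CliRunner().invoke(main, ["compress", src, cont, "--mode", "fqz",
                                  "--level", "fast"])
    assert r.exit_code == 0, r.output
    r = CliRunner().invoke(main, ["stats", cont])
    assert r.exit_code == 0 and "bits per base" in r.output
    r = CliRunner().invoke(main, ["decompress", cont, out])
    assert r.exit_code == 0
    assert open(out, "rb").read() == open(src, "rb").read()


def test_cli_simulate_writes_consistent_files(tmp_path):
    from click.testing import CliRunner
    from fqzlite.cli import main
    prefix = str(tmp_path / "sim")
    r = CliRunner().invoke(main, ["simulate", prefix, "--genome-length",
                                  "3000", "--coverage", "3", "--seed", "5"])
    assert r.exit_code == 0, r.output
    for suffix in (".fa", ".fastq", ".sam"):
        assert os.path.exists(prefix + suffix)
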