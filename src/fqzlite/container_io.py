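"""Container format, FASTQ/FASTA I/O and per-stream size accounting.

One container format serves every codec family.  Layout::

    magic "FQZ1" | version | mode | level | lossy-Q | flags
    [4-byte reference CRC32 when flags bit 0 is set]
    blocks: tag(1) | length(8, little-endian) | payload | CRC32(4)

Block tags: ``M`` metadata (JSON), ``I`` identifiers, ``S`` sequence,
``Q`` qualities, ``A`` alignments / SAM side fields, ``X`` mismatch
literals, ``L`` read lengths, ``H`` opaque SAM header.  Every payload is
checksummed, so decompression detects corruption instead of emitting
garbage; a reference-coded container refuses to decode against a
different reference.

Identifiers, bases and qualities are compressed as independent streams,
which is also what makes Table-4-style accounting (bits per identifier /
base-call / quality value) exact: the numbers reported by
:func:`stats` are block sizes, not estimates.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass

from . import id_codec, qual_codec, refmap, seq_codec
from .coder import DirectContextModel, RangeDecoder, RangeEncoder
from .qual_codec import LossyConfig, QualitySymbols, canonicalize, decanonicalize
from .samcodec import SamDecoder, SamEncoder

__all__ = [
    "Container", "StreamBreakdown", "MODES", "LEVELS",
    "read_fastq_records", "write_fastq_records", "load_reference",
    "compress_fastq", "compress_sam", "decompress", "stats",
    "build_sam_container", "read_sam_container",
]

MAGIC = b"FQZ1"
VERSION = 1
MODES = {"store": 0, "fqz": 1, "fastqz": 2, "samcomp1": 3, "samcomp2": 4}
MODE_NAMES = {v: k for k, v in MODES.items()}
LEVELS = {"fast": 0, "medium": 1, "slow": 2}
LEVEL_NAMES = {v: k for k, v in LEVELS.items()}

_FLAG_REF = 1
_FLAG_PLUS_ID = 2


@dataclass
class StreamBreakdown:
    """Per-stream accounting in the units of the field (bits per complete
    identifier, per base call, per quality value)."""
    bits_per_identifier: float
    bits_per_base: float
    bits_per_quality: float
    overall_ratio: float
    compress_rate: float          # MB/s of original data, 0 if unknown
    sizes: dict                   # tag -> compressed payload bytes
    n_records: int
    original_size: int
    compressed_size: int


@dataclass
class Container:
    mode: str
    level: str
    lossy_q: int
    flags: int
    ref_crc: int | None
    blocks: dict                  # tag -> payload bytes
    meta: dict


class ContainerError(ValueError):
    pass


def _write_container(c: Container) -> bytes:
    out = bytearray(MAGIC)
    out += bytes([VERSION, MODES[c.mode], LEVELS[c.level],
                  c.lossy_q & 0xFF, c.flags & 0xFF])
    if c.flags & _FLAG_REF:
        out += (c.ref_crc & 0xFFFFFFFF).to_bytes(4, "little")
    blocks = dict(c.blocks)
    blocks["M"] = json.dumps(c.meta, separators=(",", ":")).encode()
    for tag, payload in blocks.items():
        out += tag.encode("ascii")
        out += len(payload).to_bytes(8, "little")
        out += payload
        out += (zlib.crc32(payload) & 0xFFFFFFFF).to_bytes(4, "little")
    return bytes(out)


def _read_container(data: bytes) -> Container:
    if data[:4] != MAGIC:
        raise ContainerError("not an fqzlite container (bad magic)")
    if data[4] != VERSION:
        raise ContainerError(f"unsupported container version {data[4]}")
    mode = MODE_NAMES[data[5]]
    level = LEVEL_NAMES[data[6]]
    lossy_q = data[7]
    flags = data[8]
    pos = 9
    ref_crc = None
    if flags & _FLAG_REF:
        ref_crc = int.from_bytes(data[pos:pos + 4], "little")
        pos += 4
    blocks = {}
    while pos < len(data):
        if pos + 13 > len(data):
            raise ContainerError("truncated container block header")
        tag = chr(data[pos])
        ln = int.from_bytes(data[pos + 1:pos + 9], "little")
        payload = data[pos + 9:pos + 9 + ln]
        if len(payload) != ln:
            raise ContainerError(f"truncated payload for block {tag!r}")
        crc = int.from_bytes(data[pos + 9 + ln:pos + 13 + ln], "little")
        if (zlib.crc32(payload) & 0xFFFFFFFF) != crc:
            raise ContainerError(f"checksum mismatch in block {tag!r}")
        blocks[tag] = payload
        pos += 13 + ln
    meta = json.loads(blocks.pop("M", b"{}").decode() or "{}")
    return Container(mode, level, lossy_q, flags, ref_crc, blocks, meta)


# ---------------------------------------------------------------------------
# FASTQ text I/O (exact, 4-line records)
# ---------------------------------------------------------------------------

def read_fastq_records(path: str) -> tuple:
    """Parse a FASTQ file; returns (records, plus_has_id) where records
    are (identifier, seq, qual) and plus_has_id lists deviations from the
    dominant '+'-line style."""
    records = []
    plus_styles = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4:
        raise ContainerError(
            f"FASTQ record {len(lines) // 4}: truncated (line count not a "
            "multiple of 4)")
    for i in range(0, len(lines), 4):
        ident, seq, plus, qual = lines[i:i + 4]
        rec = i // 4
        if not ident.startswith("@"):
            raise ContainerError(f"FASTQ record {rec}: identifier must "
                                 "start with '@'")
        if not plus.startswith("+"):
            raise ContainerError(f"FASTQ record {rec}: missing '+' line")
        if len(seq) != len(qual):
            raise ContainerError(f"FASTQ record {rec}: sequence and "
                                 "quality lengths differ")
        for ch in qual:
            if not 33 <= ord(ch) <= 126:
                raise ContainerError(f"FASTQ record {rec}: quality "
                                     f"character {ch!r} out of Phred+33 range")
        plus_styles.append(plus == "+" + ident[1:])
        if plus != "+" and not plus_styles[-1]:
            raise ContainerError(f"FASTQ record {rec}: '+' line matches "
                                 "neither dialect")
        records.append((ident, seq, qual))
    return records, plus_styles


def write_fastq_records(path: str, records, plus_id: bool,
                        plus_exceptions=()) -> None:
    exc = set(plus_exceptions)
    with open(path, "w") as fh:
        for i, (ident, seq, qual) in enumerate(records):
            style = plus_id != (i in exc)
            fh.write(f"{ident}\n{seq}\n")
            fh.write(f"+{ident[1:]}\n" if style else "+\n")
            fh.write(f"{qual}\n")


def load_reference(path_or_seq) -> dict:
    """Load a reference as {name: sequence}; accepts a FASTA path, a raw
    sequence string, or an existing dict."""
    if isinstance(path_or_seq, dict):
        return path_or_seq
    s = str(path_or_seq)
    if set(s[:80].upper()) <= set("ACGTN") and "\n" not in s and \
            not s.startswith(">") and len(s) > 0 and "." not in s and "/" not in s:
        return {"ref": s.upper()}
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(s, "fasta")}


def _ref_crc(ref: dict) -> int:
    h = 0
    for name in sorted(ref):
        h = zlib.crc32(ref[name].encode(), zlib.crc32(name.encode(), h))
    return h & 0xFFFFFFFF


# ---------------------------------------------------------------------------
# read-length side stream
# ---------------------------------------------------------------------------

def _encode_lengths(lengths) -> bytes:
    enc = RangeEncoder()
    models = [DirectContextModel(256) for _ in range(5)]
    prev = 0
    for L in lengths:
        d = L - prev
        u = (d << 1) ^ (d >> 63) if d < 0 else d << 1
        for m in models:
            b = u & 0x7F
            u >>= 7
            m.encode(enc, 0, b | (0x80 if u else 0))
            if not u:
                break
        prev = L
    return enc.flush()


def _decode_lengths(data: bytes, n: int) -> list:
    if n == 0:
        return []
    dec = RangeDecoder(data)
    models = [DirectContextModel(256) for _ in range(5)]
    out = []
    prev = 0
    for _ in range(n):
        u = 0
        for i, m in enumerate(models):
            b = m.decode(dec, 0)
            u |= (b & 0x7F) << (7 * i)
            if not b & 0x80:
                break
        d = -(u >> 1) - 1 if u & 1 else u >> 1
        prev += d
        out.append(prev)
    return out


# ---------------------------------------------------------------------------
# FASTQ compression
# ---------------------------------------------------------------------------

def _qual_exceptions(orig_qual: str, qs: QualitySymbols, seq: str):
    """(quality, sequence-N) corrections for byte-exact round-tripping."""
    recon = decanonicalize(qs)
    exc_q = [[p, ord(c)] for p, (c, r) in enumerate(zip(orig_qual, recon))
             if c != r]
    n_from_q = {p for p, c in enumerate(recon) if c == "!"}
    n_actual = {p for p, c in enumerate(seq) if c == "N"}
    exc_s = [[p, seq[p]] for p in sorted(n_from_q ^ n_actual)]
    return exc_q, exc_s


def compress_fastq(in_path: str, out_path: str | None, mode: str = "fqz",
                   level: str = "medium", lossy_q: int = 1,
                   reference=None,
                   lossy_mode: str | None = None) -> StreamBreakdown:
    """Compress a FASTQ file into a container; returns the breakdown.

    ``mode`` is ``store``, ``fqz`` or ``fastqz``; ``reference`` (FASTA
    path / sequence / dict) enables fastqz reference-based coding and is
    required again for decompression.
    """
    t0 = time.monotonic()
    if mode not in ("store", "fqz", "fastqz"):
        raise ContainerError(f"mode {mode!r} does not accept FASTQ input")
    records, plus_styles = read_fastq_records(in_path)
    n_with_id = sum(plus_styles)
    plus_id = n_with_id * 2 > len(plus_styles)
    plus_exc = [i for i, s in enumerate(plus_styles) if s != plus_id]
    data = _compress_fastq_records(
        records, mode, level, lossy_q, reference, lossy_mode,
        plus_id, plus_exc)
    if out_path:
        with open(out_path, "wb") as fh:
            fh.write(data)
    import os
    orig = os.path.getsize(in_path)
    bd = stats(data, original_size=orig)
    dt = time.monotonic() - t0
    bd.compress_rate = (orig / 1e6) / dt if dt > 0 else 0.0
    return bd


def _compress_fastq_records(records, mode, level, lossy_q, reference,
                            lossy_mode, plus_id, plus_exc) -> bytes:
    n = len(records)
    lengths = [len(s) for _, s, _ in records]
    meta = {"n_records": n, "n_bases": sum(lengths),
            "n_quals": sum(lengths), "kind": "fastq"}
    if plus_exc:
        meta["plus_exceptions"] = plus_exc
    blocks: dict = {}
    flags = _FLAG_PLUS_ID if plus_id else 0
    ref_crc = None

    if lengths and min(lengths) == max(lengths):
        meta["read_length"] = lengths[0]
    else:
        blocks["L"] = _encode_lengths(lengths)

    if mode == "store":
        blocks["I"] = "\n".join(i for i, _, _ in records).encode()
        blocks["S"] = "".join(s for _, s, _ in records).encode()
        blocks["Q"] = "".join(q for _, _, q in records).encode()
        return _write_container(Container(
            mode, level, 1, flags, None, blocks, meta))

    lossless = lossy_q <= 1
    if mode == "fqz":
        cfg = _fqz_seq_config(level)
        id_mode = "string_delta" if level == "fast" else "tokenized"
        id_enc = id_codec.IdEncoder(id_mode)
        seq_enc = seq_codec.SeqEncoder(cfg)
        q_level = {"fast": 1, "medium": 2, "slow": 3}[level]
        lossy = LossyConfig(max(1, lossy_q), lossy_mode or "fqzcomp_within")
        qual_enc = qual_codec.FqzQualEncoder(q_level, lossy)
    else:
        slow = level == "slow"
        id_enc = id_codec.FastqzIdEncoder(slow)
        qual_enc = qual_codec.FastqzQualEncoder(
            slow, LossyConfig(max(1, lossy_q), lossy_mode or "fastqz_round"))
        seq_enc = None      # depends on reference presence

    exceptions = {}
    ref = None
    if mode == "fastqz" and reference is not None:
        ref = load_reference(reference)
        ref_crc = _ref_crc(ref)
        flags |= _FLAG_REF
        refseq = "".join(ref[k] for k in sorted(ref))
        meta["ref_names"] = sorted(ref)
        packed, index = refmap.build_index(refseq, table_bits=20)
        aln_records = []
        mm_enc = RangeEncoder()
        mm_models: dict = {}
        residual_enc = seq_codec.SeqEncoder(_fqz_seq_config(level))
    elif mode == "fastqz":
        seq_enc = seq_codec.FastqzSeqEncoder(level == "slow")
    else:
        pass

    for idx, (ident, seq, qual) in enumerate(records):
        id_enc.add(ident)
        qs = canonicalize(qual, seq)
        stored = qual_enc.add(qs)
        if lossless:
            exc_q, exc_s = _qual_exceptions(
                qual, QualitySymbols(stored, qs.length), seq)
            if exc_q or exc_s:
                exceptions[str(idx)] = {"q": exc_q, "s": exc_s}
        if mode == "fqz":
            seq_enc.add(seq)
        elif ref is None:
            seq_enc.add(seq)
        else:
            _ref_encode_read(seq, packed, index, aln_records,
                             mm_enc, mm_models, residual_enc)

    if exceptions:
        meta["exceptions"] = exceptions
    blocks["I"] = id_enc.finish()
    blocks["Q"] = qual_enc.finish()
    if mode == "fastqz" and ref is not None:
        blocks["A"] = refmap.code_alignments(aln_records, level == "slow")
        blocks["X"] = mm_enc.flush()
        blocks["S"] = residual_enc.finish()
    else:
        blocks["S"] = seq_enc.finish()
    return _write_container(Container(
        mode, level, max(1, lossy_q), flags, ref_crc, blocks, meta))


def _fqz_seq_config(level: str) -> seq_codec.SeqModelConfig:
    if level == "fast":
        return seq_codec.SeqModelConfig(k=12)
    if level == "medium":
        return seq_codec.SeqModelConfig(k=14)
    return seq_codec.SeqModelConfig(k=16, hashed=True, hash_bits=26,
                                    use_revcomp=True, dual_order7=True)


def _ref_encode_read(seq, packed, index, aln_records, mm_enc, mm_models,
                     residual_enc) -> None:
    rec = refmap.align_read(seq, index, packed)
    if len(seq) > 254 and not rec.unmatched:
        rec = refmap.AlignmentRecord(True, read_len=len(seq))
    aln_records.append(rec)
    if rec.unmatched:
        residual_enc.add(seq)
        return
    codes = refmap._read_codes(seq)
    if rec.dir:
        codes = refmap.revcomp_codes(codes)
    covered = set(refmap.matched_positions(rec))
    refc = packed.codes
    for i in range(rec.read_len):
        if i in covered:
            continue
        rp = rec.ptr + i
        key = int(refc[rp]) if 0 <= rp < len(refc) else 4
        _mm_encode(mm_enc, mm_models, key, int(codes[i]))


def _mm_encode(enc, models, key, sym):
    f = models.get(key)
    if f is None:
        f = [0, 0, 0, 0]
        models[key] = f
    cum = sym
    for i in range(sym):
        cum += f[i]
    enc.encode_freq(cum, f[sym] + 1, f[0] + f[1] + f[2] + f[3] + 4)
    f[sym] += 8
    if f[sym] > 247:
        for z in range(4):
            f[z] = (f[z] + 1) >> 1


def _mm_decode(dec, models, key):
    f = models.get(key)
    if f is None:
        f = [0, 0, 0, 0]
        models[key] = f
    tot = f[0] + f[1] + f[2] + f[3] + 4
    target = dec.decode_target(tot)
    cum = 0
    for s in range(4):
        nxt = cum + f[s] + 1
        if target < nxt:
            break
        cum = nxt
    dec.decode_update(cum, f[s] + 1)
    f[s] += 8
    if f[s] > 247:
        for z in range(4):
            f[z] = (f[z] + 1) >> 1
    return s


# ---------------------------------------------------------------------------
# decompression
# ---------------------------------------------------------------------------

def decompress(in_path_or_bytes, out_path: str | None = None,
               reference=None):
    """Decompress a container; FASTQ modes return/write FASTQ text, SAM
    modes return (header, records) or write SAM text."""
    data = in_path_or_bytes
    if isinstance(data, str):
        with open(data, "rb") as fh:
            data = fh.read()
    c = _read_container(data)
    if c.mode in ("samcomp1", "samcomp2"):
        header, records = _decode_sam_container(c, reference)
        if out_path:
            from .samcodec import write_sam
            write_sam(out_path, header, records)
        return header, records
    records = _decode_fastq_container(c, reference)
    if out_path:
        write_fastq_records(out_path, records,
                            bool(c.flags & _FLAG_PLUS_ID),
                            c.meta.get("plus_exceptions", ()))
    return records


def _check_reference(c: Container, reference) -> dict:
    if not c.flags & _FLAG_REF:
        return {}
    if reference is None:
        raise ContainerError(
            "container was reference-coded; pass the same reference")
    ref = load_reference(reference)
    if _ref_crc(ref) != c.ref_crc:
        raise ContainerError(
            "reference does not match the one used for compression")
    return ref


def _decode_fastq_container(c: Container, reference=None) -> list:
    n = c.meta["n_records"]
    if "read_length" in c.meta:
        lengths = [c.meta["read_length"]] * n
    else:
        lengths = _decode_lengths(c.blocks.get("L", b""), n)
    if c.mode == "store":
        ids = c.blocks["I"].decode().split("\n") if n else []
        seqs, quals = [], []
        p = 0
        S = c.blocks["S"].decode()
        Q = c.blocks["Q"].decode()
        for L in lengths:
            seqs.append(S[p:p + L])
            quals.append(Q[p:p + L])
            p += L
        return list(zip(ids, seqs, quals))

    ref = _check_reference(c, reference)
    level = c.level
    if c.mode == "fqz":
        id_mode = "string_delta" if level == "fast" else "tokenized"
        id_dec = id_codec.IdDecoder(c.blocks["I"], id_mode) if n else None
        q_level = {"fast": 1, "medium": 2, "slow": 3}[level]
        qual_dec = qual_codec.FqzQualDecoder(c.blocks["Q"], q_level) if n else None
        seq_dec = seq_codec.SeqDecoder(c.blocks["S"], _fqz_seq_config(level)) \
            if sum(lengths) else None
        ref_mode = False
    else:
        slow = level == "slow"
        id_dec = id_codec.FastqzIdDecoder(c.blocks["I"], slow) if n else None
        qual_dec = qual_codec.FastqzQualDecoder(c.blocks["Q"], slow) if n else None
        ref_mode = bool(c.flags & _FLAG_REF)
        if ref_mode:
            refseq = "".join(ref[k] for k in sorted(ref))
            packed = refmap.pack_reference(refseq)
            aln = refmap.decode_alignments(c.blocks["A"], lengths, slow)
            mm_dec = RangeDecoder(c.blocks["X"]) if c.blocks["X"] else None
            mm_models: dict = {}
            residual = seq_codec.SeqDecoder(
                c.blocks["S"], _fqz_seq_config(level)) if c.blocks["S"] else None
        else:
            seq_dec = seq_codec.FastqzSeqDecoder(c.blocks["S"], slow) \
                if sum(lengths) else None

    exceptions = c.meta.get("exceptions", {})
    out = []
    for i in range(n):
        L = lengths[i]
        ident = id_dec.get()
        qs = qual_dec.get(L)
        qual = decanonicalize(qs)
        if c.mode == "fqz" or not ref_mode:
            seq = seq_dec.get(L) if L else ""
        else:
            seq = _ref_decode_read(aln[i], packed, mm_dec, mm_models,
                                   residual, L)
        seq = "".join("N" if q == "!" else b for b, q in zip(seq, qual))
        exc = exceptions.get(str(i))
        if exc:
            if exc["q"]:
                ql = list(qual)
                for p, o in exc["q"]:
                    ql[p] = chr(o)
                qual = "".join(ql)
            if exc["s"]:
                sl = list(seq)
                for p, b in exc["s"]:
                    sl[p] = b
                seq = "".join(sl)
        out.append((ident, seq, qual))
    return out


def _ref_decode_read(rec, packed, mm_dec, mm_models, residual, L) -> str:
    if rec.unmatched:
        return residual.get(L)
    covered = set(refmap.matched_positions(rec))
    refc = packed.codes
    codes = []
    for i in range(L):
        rp = rec.ptr + i
        in_ref = 0 <= rp < len(refc)
        if i in covered:
            codes.append(int(refc[rp]))
        else:
            key = int(refc[rp]) if in_ref else 4
            codes.append(_mm_decode(mm_dec, mm_models, key))
    import numpy as np
    arr = np.asarray(codes, dtype=np.uint8)
    if rec.dir:
        arr = refmap.revcomp_codes(arr)
    return "".join("ACGT"[int(x)] for x in arr)


# ---------------------------------------------------------------------------
# SAM containers
# ---------------------------------------------------------------------------

def build_sam_container(records, mode: str, ref=None,
                        header_text: str = "", level: str = "medium") -> bytes:
    refd = load_reference(ref) if ref is not None else None
    enc = SamEncoder(mode, refd)
    for r in records:
        enc.add(r)
    blocks = enc.finish()
    meta = enc.meta()
    meta["kind"] = "sam"
    meta["n_bases"] = sum(len(r.seq) for r in records if r.seq != "*")
    meta["n_quals"] = sum(len(r.qual) for r in records if r.qual != "*")
    out_blocks = {"I": blocks["ID"], "A": blocks["FLD"],
                  "S": blocks["SEQ"], "Q": blocks["QUAL"],
                  "H": header_text.encode()}
    flags = 0
    ref_crc = None
    if refd:
        flags |= _FLAG_REF
        ref_crc = _ref_crc(refd)
    return _write_container(Container(
        mode, level, 1, flags, ref_crc, out_blocks, meta))


def compress_sam(in_path: str, out_path: str | None, mode: str = "samcomp1",
                 reference=None) -> StreamBreakdown:
    """Compress a SAM text file with samcomp1/samcomp2."""
    t0 = time.monotonic()
    from .samcodec import read_sam
    header, records = read_sam(in_path)
    data = build_sam_container(records, mode, reference, header)
    if out_path:
        with open(out_path, "wb") as fh:
            fh.write(data)
    import os
    orig = os.path.getsize(in_path)
    bd = stats(data, original_size=orig)
    dt = time.monotonic() - t0
    bd.compress_rate = (orig / 1e6) / dt if dt > 0 else 0.0
    return bd


def _decode_sam_container(c: Container, reference=None):
    ref = _check_reference(c, reference)
    if c.mode == "samcomp2" and not ref:
        ref = {}
    blocks = {"ID": c.blocks["I"], "FLD": c.blocks["A"],
              "SEQ": c.blocks["S"], "QUAL": c.blocks["Q"]}
    dec = SamDecoder(blocks, c.meta, c.mode, ref)
    records = [dec.get() for _ in range(c.meta["n_records"])]
    return c.blocks.get("H", b"").decode(), records


def read_sam_container(data: bytes, reference=None):
    return _decode_sam_container(_read_container(data), reference)


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------

def stats(path_or_bytes, original_size: int | None = None) -> StreamBreakdown:
    """Per-stream size accounting from a container's block sizes."""
    data = path_or_bytes
    if isinstance(data, str):
        with open(data, "rb") as fh:
            data = fh.read()
    c = _read_container(data)
    sizes = {tag: len(payload) for tag, payload in c.blocks.items()}
    n = c.meta.get("n_records", 0)
    n_bases = c.meta.get("n_bases", 0)
    n_quals = c.meta.get("n_quals", 0)
    id_bits = sizes.get("I", 0) * 8
    base_bits = (sizes.get("S", 0) + sizes.get("A", 0) +
                 sizes.get("X", 0)) * 8
    qual_bits = sizes.get("Q", 0) * 8
    if original_size is None:
        original_size = 0
    return StreamBreakdown(
        bits_per_identifier=id_bits / n if n else 0.0,
        bits_per_base=base_bits / n_bases if n_bases else 0.0,
        bits_per_quality=qual_bits / n_quals if n_quals else 0.0,
        overall_ratio=(len(data) / original_size) if original_size else 0.0,
        compress_rate=0.0,
        sizes=sizes,
        n_records=n,
        original_size=original_size,
        compressed_size=len(data),
    )
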