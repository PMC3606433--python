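"""Reference-based read coding (fastqz style).

The reference is packed 4 bases per byte (A=0, C=1, G=2, T=3, N deleted)
and split into non-overlapping 32-base groups.  A hash index maps each
group to its ordinal: 2^b slots holding a pointer and a 5-bit checksum,
inserted with linear probing over at most 8 consecutive slots (pointers
that find no slot are discarded — a coverage loss, never an error).

Reads are aligned by hashing every 32-base window on both strands and
looking the hashes up in the index; candidates are scored by the position
of their fourth mismatch (ties broken by the third, second, first).
A successful alignment is stored as up to four mismatch positions, a
direction bit and a reference pointer; the matched bases are deleted from
the sequence stream and reinserted during decompression.  An unmatched
read is serialized as a single 0 byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coder import BitContextModel, RangeDecoder, RangeEncoder

__all__ = [
    "PackedReference", "GroupIndex", "AlignmentRecord",
    "pack_reference", "unpack_reference", "build_index", "align_read",
    "serialize_records", "deserialize_records", "code_alignments",
    "decode_alignments", "simulate_index_discard",
]

GROUP = 32
PROBE = 8
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass
class PackedReference:
    """N-stripped reference, 2-bit codes packed 4 per byte."""
    data: bytes                  # packed bases
    length: int                  # retained (non-N) bases
    n_map: list                  # (position in stripped ref, N-run length)
    codes: np.ndarray = field(repr=False, default=None)  # uint8 per base

    def base(self, i: int) -> str:
        return _BASES[int(self.codes[i])]


@dataclass
class GroupIndex:
    """Linear-probe hash index over non-overlapping 32-base groups."""
    table_bits: int
    pointers: np.ndarray         # uint32, group ordinal + 1 (0 = empty)
    checksums: np.ndarray        # uint8, 5 bits used
    n_groups: int
    n_discarded: int

    @property
    def discard_fraction(self) -> float:
        return self.n_discarded / self.n_groups if self.n_groups else 0.0


@dataclass
class AlignmentRecord:
    """fastqz alignment code for one read.

    ``m`` holds four 1-based mismatch positions in ascending order with
    read length + 1 filling unused slots; ``dir`` is 0 for a forward and
    1 for a reverse-complement match; ``ptr`` is the reference start (in
    N-stripped coordinates) of the matching window.
    """
    unmatched: bool
    m: tuple = (0, 0, 0, 0)
    dir: int = 0
    ptr: int = 0
    read_len: int = 0


def pack_reference(seq: str) -> PackedReference:
    """Pack a reference sequence, deleting N runs but recording them."""
    codes = []
    n_map = []
    run = 0
    for ch in seq:
        c = _CODE.get(ch)
        if c is None:
            if ch != "N":
                raise ValueError(f"reference base {ch!r} not in A,C,G,T,N")
            run += 1
            continue
        if run:
            n_map.append((len(codes), run))
            run = 0
        codes.append(c)
    if run:
        n_map.append((len(codes), run))
    arr = np.asarray(codes, dtype=np.uint8)
    packed = bytearray()
    for i in range(0, len(arr) - len(arr) % 4, 4):
        packed.append(int(arr[i]) << 6 | int(arr[i + 1]) << 4 |
                      int(arr[i + 2]) << 2 | int(arr[i + 3]))
    tail = arr[len(arr) - len(arr) % 4:]
    if len(tail):
        b = 0
        for j, c in enumerate(tail):
            b |= int(c) << (6 - 2 * j)
        packed.append(b)
    return PackedReference(bytes(packed), len(arr), n_map, arr)


def unpack_reference(pr: PackedReference, with_n: bool = False) -> str:
    """Reconstruct the (optionally N-restored) reference string."""
    out = []
    for i in range(pr.length):
        b = pr.data[i // 4]
        out.append(_BASES[(b >> (6 - 2 * (i % 4))) & 3])
    if with_n:
        for pos, run in reversed(pr.n_map):
            out.insert(pos, "N" * run)
    return "".join(out)


def _group_hash(codes: np.ndarray) -> int:
    """64-bit mixing hash of a 32-base group (2-bit codes)."""
    v = 0
    for c in codes:
        v = (v << 2) | int(c)
    v = (v * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    v ^= v >> 29
    v = (v * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    v ^= v >> 32
    return v


def build_index(ref, table_bits: int = 20):
    """Pack a reference and hash-index its 32-base groups.

    ``ref`` may be a sequence string or an existing
    :class:`PackedReference`.  Returns ``(PackedReference, GroupIndex)``.
    A reference shorter than one group yields an empty (valid) index.
    """
    pr = ref if isinstance(ref, PackedReference) else pack_reference(ref)
    n_groups = pr.length // GROUP
    size = 1 << table_bits
    mask = size - 1
    pointers = np.zeros(size, dtype=np.uint32)
    checksums = np.zeros(size, dtype=np.uint8)
    discarded = 0
    codes = pr.codes
    for g in range(n_groups):
        h = _group_hash(codes[g * GROUP:(g + 1) * GROUP])
        slot = h & mask
        chk = (h >> table_bits) & 31
        for j in range(PROBE):
            s = (slot + j) & mask
            if pointers[s] == 0:
                pointers[s] = g + 1
                checksums[s] = chk
                break
        else:
            discarded += 1
    return pr, GroupIndex(table_bits, pointers, checksums, n_groups, discarded)


def simulate_index_discard(load: float, table_bits: int = 18,
                           probes: int = PROBE, seed: int = 0) -> float:
    """Fraction of pointers discarded when ``load * 2^bits`` uniformly
    hashed keys are inserted with ``probes``-slot linear probing."""
    rng = np.random.default_rng(seed)
    n = 1 << table_bits
    mask = n - 1
    table = np.zeros(n, dtype=bool)
    keys = rng.integers(0, n, size=int(load * n))
    disc = 0
    for k in keys:
        k = int(k)
        for j in range(probes):
            if not table[(k + j) & mask]:
                table[(k + j) & mask] = True
                break
        else:
            disc += 1
    return disc / max(1, len(keys))


def _read_codes(read: str) -> np.ndarray:
    return np.frombuffer(
        read.encode("ascii").translate(_TRANS), dtype=np.uint8)


# byte translation table: A,N->0 C->1 G->2 T->3
_TRANS = bytes(
    {65: 0, 67: 1, 71: 2, 84: 3, 78: 0}.get(i, 255) for i in range(256))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].copy()


MAX_CANDIDATES = 16     # index hits examined per strand


def _mismatch_positions(read_codes, ref_codes, start):
    seg = ref_codes[start:start + len(read_codes)]
    return np.nonzero(seg != read_codes)[0]


def _evaluate(read_codes, ref_codes, start, L):
    """First four 1-based mismatch positions (L+1 padding), or None if the
    window falls outside the reference."""
    if start < 0 or start + L > len(ref_codes):
        return None
    mm = _mismatch_positions(read_codes, ref_codes, start)
    m = [L + 1] * 4
    for i in range(min(4, len(mm))):
        m[i] = int(mm[i]) + 1
    if len(mm) > 4:
        m[3] = int(mm[3]) + 1
    return tuple(m)


def align_read(read: str, idx: GroupIndex, ref: PackedReference) -> AlignmentRecord:
    """Find the best reference window for a read on either strand.

    Candidates come from hashing each 32-base window of the read (both
    orientations) into the group index; they are ranked by the position of
    the fourth mismatch, ties broken by the third, second, first.  A best
    fourth mismatch before half the read length means the read is coded as
    unmatched.
    """
    L = len(read)
    if L < GROUP or idx.n_groups == 0:
        return AlignmentRecord(True, read_len=L)
    fwd = _read_codes(read)
    if fwd.max() > 3:
        return AlignmentRecord(True, read_len=L)
    rev = revcomp_codes(fwd)
    mask = (1 << idx.table_bits) - 1
    ref_codes = ref.codes
    best = None
    best_key = None
    for direction, codes in ((0, fwd), (1, rev)):
        tried = set()
        hits = 0
        for j in range(0, L - GROUP + 1):
            if hits >= MAX_CANDIDATES:
                break
            h = _group_hash(codes[j:j + GROUP])
            slot = h & mask
            chk = (h >> idx.table_bits) & 31
            for p in range(PROBE):
                s = (slot + p) & mask
                ptr = int(idx.pointers[s])
                if ptr == 0:
                    break
                if int(idx.checksums[s]) != chk:
                    continue
                start = (ptr - 1) * GROUP - j
                if start in tried:
                    continue
                tried.add(start)
                hits += 1
                m = _evaluate(codes, ref_codes, start, L)
                if m is None:
                    continue
                # rank: larger m4, then m3, m2, m1
                key = (m[3], m[2], m[1], m[0])
                if best_key is None or key > best_key:
                    best_key = key
                    best = AlignmentRecord(False, m, direction, start, L)
    if best is None or best.m[3] < (L + 1) / 2:
        return AlignmentRecord(True, read_len=L)
    return best


def matched_positions(rec: AlignmentRecord):
    """0-based read positions (in match orientation) taken from the
    reference: everything before the fourth mismatch except the recorded
    mismatches; the tail from the fourth mismatch on stays literal."""
    if rec.unmatched:
        return []
    L = rec.read_len
    stop = min(rec.m[3] - 1, L)          # m4 position itself is literal
    mismatches = {p - 1 for p in rec.m[:3] if p <= L}
    return [i for i in range(stop) if i not in mismatches]


# ---------------------------------------------------------------------------
# alignment-record serialization and coding
# ---------------------------------------------------------------------------

def serialize_records(records) -> bytes:
    """Fast-mode byte serialization: 0 for unmatched, else
    m1..m4, dir, ptr (4 bytes little-endian).  Requires read length <= 254
    (longer reads are always coded unmatched upstream)."""
    out = bytearray()
    for r in records:
        if r.unmatched:
            out.append(0)
            continue
        for v in r.m:
            if not 1 <= v <= 255:
                raise ValueError("mismatch position exceeds one byte")
            out.append(v)
        out.append(r.dir)
        out += int(r.ptr).to_bytes(4, "little")
    return bytes(out)


def deserialize_records(data: bytes, read_lens) -> list:
    records = []
    pos = 0
    for L in read_lens:
        if data[pos] == 0:
            records.append(AlignmentRecord(True, read_len=L))
            pos += 1
            continue
        m = tuple(data[pos:pos + 4])
        d = data[pos + 4]
        ptr = int.from_bytes(data[pos + 5:pos + 9], "little")
        pos += 9
        records.append(AlignmentRecord(False, m, d, ptr, L))
    return records


def code_alignments(records, slow: bool = False) -> bytes:
    """Serialize alignment records; slow mode arithmetic-codes the bytes
    under a direct context model keyed by the parse state, the previous
    bits of the current byte, and the high 6 bits of the previous byte
    (dropped for the two low pointer bytes)."""
    raw = serialize_records(records)
    if not slow:
        return raw
    enc = RangeEncoder()
    cm = BitContextModel()
    _code_aln(enc, cm, records, raw=None, encode=True)
    return enc.flush()


def _aln_field_states(r):
    """(state id, use_prev_byte) for the 8 bytes after the first of a
    matched record: m2..m4, dir, then the 4 little-endian pointer bytes
    (the 2 low pointer bytes drop the previous-byte context)."""
    return [(1, True), (2, True), (3, True),              # m2..m4
            (4, True),                                    # dir
            (5, False), (6, False), (7, True), (8, True)] # ptr LE bytes


def _code_aln(rc, cm, records, raw, encode):
    """Shared encode/decode walk; for decode, ``records`` is a list of
    read lengths and reconstructed records are returned."""
    out = []
    prev_byte = 0

    def code_byte(state, use_prev, byte=None):
        nonlocal prev_byte
        part = 1
        for k in range(8):
            key = (state << 20) | (part << 8) | ((prev_byte >> 2) if use_prev else 0)
            p = cm.predict(key)
            if encode:
                bit = (byte >> (7 - k)) & 1
                rc.encode_bit(bit, p)
            else:
                bit = rc.decode_bit(p)
            cm.update(key, bit)
            part = (part << 1) | bit
        value = part & 0xFF
        prev_byte = value
        return value

    if encode:
        for r in records:
            if r.unmatched:
                code_byte(0, True, 0)
                continue
            fields = list(r.m) + [r.dir] + list(int(r.ptr).to_bytes(4, "little"))
            code_byte(0, True, fields[0])
            for (state, use_prev), v in zip(_aln_field_states(r), fields[1:]):
                code_byte(state, use_prev, v)
        return None
    for L in records:
        first = code_byte(0, True)
        if first == 0:
            out.append(AlignmentRecord(True, read_len=L))
            continue
        rest = [code_byte(state, use_prev)
                for state, use_prev in _aln_field_states(None)]
        vals = [first] + rest
        m = tuple(vals[:4])
        d = vals[4]
        ptr = int.from_bytes(bytes(vals[5:9]), "little")
        out.append(AlignmentRecord(False, m, d, ptr, L))
    return out


def decode_alignments(data: bytes, read_lens, slow: bool = False) -> list:
    """Inverse of :func:`code_alignments` given the read lengths."""
    read_lens = list(read_lens)
    if not read_lens:
        return []
    if not slow:
        return deserialize_records(data, read_lens)
    rc = RangeDecoder(data)
    cm = BitContextModel()
    return _code_aln(rc, cm, read_lens, raw=None, encode=False)
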