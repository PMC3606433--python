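"""Base-call compression.

The fqzcomp path codes bases 0..3 (A,C,G,T; N is coded as 0 and restored
from its zero quality) under an order-k context model — the previous k
bases packed two bits each.  With enough depth and a small enough genome
the model effectively memorises the genomic k-mers, which is where the
strong compression of deep data sets comes from.  Options: updating each
context's reverse complement as well, and a second fixed order-7 model
with per-symbol selection of whichever model currently holds the
strongest bias (no mixing).

The fastqz path packs 3 or 4 bases per byte with the self-synchronizing
code A=1, T=2, C=3, G=4 and then codes the packed bytes with a stack of
six predictors (direct orders 0-2, an indirect order-3 model, an order-4
secondary estimator and an order-5 match model) under a logistic mixer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coder import (
    BitContextModel, BitHistoryModel, MatchModel, Mixer, RangeDecoder,
    RangeEncoder, SSE,
)

__all__ = [
    "SeqModelConfig", "PackedBases",
    "base_to_sym", "sym_to_base",
    "SeqEncoder", "SeqDecoder", "seq_encode", "seq_decode",
    "select_model", "pack_bases", "unpack_bases", "group_sizes",
    "FastqzSeqEncoder", "FastqzSeqDecoder", "fastqz_seq_model_stack",
]

_BASE_SYM = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}
_SYM_BASE = "ACGT"
_COMP = [3, 2, 1, 0]          # A<->T, C<->G on 2-bit codes


def base_to_sym(base: str) -> int:
    try:
        return _BASE_SYM[base]
    except KeyError:
        raise ValueError(f"unsupported base {base!r}") from None


def sym_to_base(sym: int) -> str:
    return _SYM_BASE[sym]


@dataclass
class SeqModelConfig:
    """Order-k model configuration for the fqzcomp sequence coder."""
    k: int = 12
    use_revcomp: bool = False
    dual_order7: bool = False
    hashed: bool = False          # hash contexts into 2^hash_bits slots
    hash_bits: int = 24

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError("context order k must be in 1..32")

    @property
    def table_slots(self) -> int:
        if self.hashed:
            return 1 << self.hash_bits
        return 4 ** self.k


def select_model(p_orderk, p_order7) -> int:
    """Pick the model with the strongest single-symbol bias (0: order-k,
    1: order-7); ties go to the order-k model.  Depends only on the model
    state, so encoder and decoder always agree."""
    return 1 if max(p_order7) > max(p_orderk) else 0


class _FlatModel:
    """Flat-array order-k base model: 4 counters of 8 bits per context.

    The +4 increment keeps a fresh context close to uniform after a
    single observation (i.i.d. input then still codes at ~2 bits/base)
    while a genuinely deterministic context converges within a few
    observations."""

    INC = 4
    LIMIT = 251          # halve before a counter can exceed 255

    def __init__(self, slots: int) -> None:
        self.counts = np.zeros(slots * 4, dtype=np.uint8)


class SeqEncoder:
    """Streaming fqzcomp sequence encoder (read-at-a-time).

    The context register is reset at each read start so records stay
    independently decodable in order.
    """

    def __init__(self, cfg: SeqModelConfig | None = None) -> None:
        self.cfg = cfg or SeqModelConfig()
        self.model = _FlatModel(self.cfg.table_slots)
        self.model7 = _FlatModel(4 ** 7) if self.cfg.dual_order7 else None
        self.enc = RangeEncoder()
        self.bases = 0

    def _ctx_slot(self, ctx: int) -> int:
        if self.cfg.hashed:
            return ((ctx * 0x9E3779B97F4A7C15) >> (64 - self.cfg.hash_bits)) \
                & (self.cfg.table_slots - 1)
        return ctx

    def add(self, seq: str) -> None:
        cfg = self.cfg
        enc = self.enc
        counts = self.model.counts
        counts7 = self.model7.counts if self.model7 is not None else None
        kmask = (1 << (2 * cfg.k)) - 1
        mask7 = (1 << 14) - 1
        rcshift = 2 * (cfg.k - 1)
        ctx = 0
        ctx7 = 0
        rcctx = 0
        inc, limit = _FlatModel.INC, _FlatModel.LIMIT
        for ch in seq:
            s = _BASE_SYM.get(ch)
            if s is None:
                raise ValueError(f"unsupported base {ch!r}")
            i0 = self._ctx_slot(ctx) * 4
            f = counts[i0:i0 + 4].tolist()
            if counts7 is not None:
                j0 = (ctx7 & mask7) * 4
                f7 = counts7[j0:j0 + 4].tolist()
                t, t7 = sum(f) + 4, sum(f7) + 4
                if (max(f7) + 1) * t > (max(f) + 1) * t7:   # stronger bias wins
                    cum = f7[0] + 1 if s > 0 else 0
                    if s > 1:
                        cum += f7[1] + 1
                    if s > 2:
                        cum += f7[2] + 1
                    enc.encode_freq(cum, f7[s] + 1, t7)
                else:
                    cum = f[0] + 1 if s > 0 else 0
                    if s > 1:
                        cum += f[1] + 1
                    if s > 2:
                        cum += f[2] + 1
                    enc.encode_freq(cum, f[s] + 1, t)
                f7[s] += inc
                if f7[s] > limit:
                    for z in range(4):
                        f7[z] = (f7[z] + 1) >> 1
                counts7[j0:j0 + 4] = f7
                ctx7 = ((ctx7 << 2) | s) & mask7
            else:
                cum = f[0] + 1 if s > 0 else 0
                if s > 1:
                    cum += f[1] + 1
                if s > 2:
                    cum += f[2] + 1
                enc.encode_freq(cum, f[s] + 1, sum(f) + 4)
            f[s] += inc
            if f[s] > limit:
                for z in range(4):
                    f[z] = (f[z] + 1) >> 1
            counts[i0:i0 + 4] = f
            if cfg.use_revcomp:
                # observing context C then s also teaches revcomp(C + s)
                rs = _COMP[s]
                rctx = (rcctx >> 2) | (rs << rcshift)
                ri = self._ctx_slot(rctx & kmask) * 4
                rsym = _COMP[(ctx >> rcshift) & 3]
                rf = counts[ri:ri + 4].tolist()
                rf[rsym] += inc
                if rf[rsym] > limit:
                    for z in range(4):
                        rf[z] = (rf[z] + 1) >> 1
                counts[ri:ri + 4] = rf
                rcctx = rctx
            ctx = ((ctx << 2) | s) & kmask
            self.bases += 1

    def finish(self) -> bytes:
        return self.enc.flush()


class SeqDecoder:
    """Streaming inverse of :class:`SeqEncoder`."""

    def __init__(self, data: bytes, cfg: SeqModelConfig | None = None) -> None:
        self.cfg = cfg or SeqModelConfig()
        self.model = _FlatModel(self.cfg.table_slots)
        self.model7 = _FlatModel(4 ** 7) if self.cfg.dual_order7 else None
        self.dec = RangeDecoder(data)

    def _ctx_slot(self, ctx: int) -> int:
        if self.cfg.hashed:
            return ((ctx * 0x9E3779B97F4A7C15) >> (64 - self.cfg.hash_bits)) \
                & (self.cfg.table_slots - 1)
        return ctx

    def get(self, length: int) -> str:
        cfg = self.cfg
        dec = self.dec
        counts = self.model.counts
        counts7 = self.model7.counts if self.model7 is not None else None
        kmask = (1 << (2 * cfg.k)) - 1
        mask7 = (1 << 14) - 1
        rcshift = 2 * (cfg.k - 1)
        ctx = 0
        ctx7 = 0
        rcctx = 0
        inc, limit = _FlatModel.INC, _FlatModel.LIMIT
        out = []
        for _ in range(length):
            i0 = self._ctx_slot(ctx) * 4
            f = counts[i0:i0 + 4].tolist()
            use7 = False
            if counts7 is not None:
                j0 = (ctx7 & mask7) * 4
                f7 = counts7[j0:j0 + 4].tolist()
                t, t7 = sum(f) + 4, sum(f7) + 4
                use7 = (max(f7) + 1) * t > (max(f) + 1) * t7
            if use7:
                target = dec.decode_target(t7)
                cum = 0
                for s in range(4):
                    nxt = cum + f7[s] + 1
                    if target < nxt:
                        break
                    cum = nxt
                dec.decode_update(cum, f7[s] + 1)
            else:
                tot = sum(f) + 4
                target = dec.decode_target(tot)
                cum = 0
                for s in range(4):
                    nxt = cum + f[s] + 1
                    if target < nxt:
                        break
                    cum = nxt
                dec.decode_update(cum, f[s] + 1)
            if counts7 is not None:
                f7[s] += inc
                if f7[s] > limit:
                    for z in range(4):
                        f7[z] = (f7[z] + 1) >> 1
                counts7[j0:j0 + 4] = f7
                ctx7 = ((ctx7 << 2) | s) & mask7
            f[s] += inc
            if f[s] > limit:
                for z in range(4):
                    f[z] = (f[z] + 1) >> 1
            counts[i0:i0 + 4] = f
            if cfg.use_revcomp:
                rs = _COMP[s]
                rctx = (rcctx >> 2) | (rs << rcshift)
                ri = self._ctx_slot(rctx & kmask) * 4
                rsym = _COMP[(ctx >> rcshift) & 3]
                rf = counts[ri:ri + 4].tolist()
                rf[rsym] += inc
                if rf[rsym] > limit:
                    for z in range(4):
                        rf[z] = (rf[z] + 1) >> 1
                counts[ri:ri + 4] = rf
                rcctx = rctx
            ctx = ((ctx << 2) | s) & kmask
            out.append(_SYM_BASE[s])
        return "".join(out)


def seq_encode(seqs, cfg: SeqModelConfig | None = None) -> bytes:
    """Encode an iterable of reads; lossless given the quality stream
    (N positions are restored from quality 0)."""
    enc = SeqEncoder(cfg)
    for s in seqs:
        enc.add(s)
    return enc.finish()


def seq_decode(data: bytes, lengths,
               cfg: SeqModelConfig | None = None) -> list:
    """Inverse of :func:`seq_encode` given the read lengths."""
    lengths = list(lengths)
    if not lengths or sum(lengths) == 0:
        return ["" for _ in lengths]
    dec = SeqDecoder(data, cfg)
    return [dec.get(n) for n in lengths]


# ---------------------------------------------------------------------------
# fastqz base packing
# ---------------------------------------------------------------------------

_PACK_CODE = {"A": 1, "T": 2, "C": 3, "G": 4, "N": 1}
_PACK_BASE = " ATCG"


@dataclass
class PackedBases:
    """3/4-base-per-byte packing of one read (plus a remainder tail code).

    Full groups occupy byte values 63..255 (63..84: three bases, 85..255:
    four); values 1..62 are terminal remainder codes: 1..4 a single base,
    5..20 two bases, 21..62 a final three-base group whose packed value
    stayed below 63.
    """
    data: bytes
    n_bases: int


def pack_bases(seq: str) -> PackedBases:
    """Self-synchronizing packing with codes A=1, T=2, C=3, G=4.

    Three bases are accumulated as ``v = ((c1*4)+c2)*4+c3``; a fourth is
    appended iff ``v*4 + c4 <= 255``.  Any sequence starting G, CG or CCG
    (and the corner case CCC before a G) therefore forms a 3-base group.
    """
    out = bytearray()
    n = len(seq)
    i = 0
    while n - i >= 3:
        c1 = _PACK_CODE[seq[i]]
        c2 = _PACK_CODE[seq[i + 1]]
        c3 = _PACK_CODE[seq[i + 2]]
        v = (c1 * 4 + c2) * 4 + c3
        if n - i >= 4 and v * 4 + _PACK_CODE[seq[i + 3]] <= 255:
            out.append(v * 4 + _PACK_CODE[seq[i + 3]])
            i += 4
        elif v >= 63:
            out.append(v)
            i += 3
        else:
            # fewer than 4 bases left and the 3-base value collides with
            # the remainder region: emit it as a terminal remainder code
            out.append(v)
            i += 3
            break
    rem = n - i
    if rem == 1:
        out.append(_PACK_CODE[seq[i]])
    elif rem == 2:
        out.append(5 + (_PACK_CODE[seq[i]] - 1) * 4 + (_PACK_CODE[seq[i + 1]] - 1))
    return PackedBases(bytes(out), n)


def _decode_group(v: int) -> list:
    """Digits of v in base 4 with digit set {1,2,3,4}."""
    digits = []
    while v > 0:
        d = v % 4
        if d == 0:
            d = 4
        digits.append(d)
        v = (v - d) // 4
    return digits[::-1]


def unpack_bases(pb: PackedBases) -> str:
    """Inverse of :func:`pack_bases`.

    Every byte value >= 1 decodes uniquely: the digit expansion in base 4
    over the digit set {1,2,3,4} has 4 digits for 85..255, 3 for 21..84,
    2 for 5..20 and 1 for 1..4, and the remainder codes were chosen to
    coincide with that expansion.
    """
    out = []
    remaining = pb.n_bases
    for v in pb.data:
        digits = _decode_group(v)
        for d in digits:
            out.append(_PACK_BASE[d])
        remaining -= len(digits)
    if remaining != 0:
        raise ValueError("packed data inconsistent with base count")
    return "".join(out)


def group_sizes(data: bytes) -> list:
    """Number of bases decoded from each packed byte (parse boundaries)."""
    return [len(_decode_group(v)) for v in data]


# ---------------------------------------------------------------------------
# fastqz slow-mode model stack over packed bytes
# ---------------------------------------------------------------------------

def _h32(*xs) -> int:
    h = 0x811C9DC5
    for x in xs:
        h = ((h ^ x) * 0x01000193) & 0xFFFFFFFF
    return h >> 4


class _SeqStack:
    """Mixer over direct orders 0-2, indirect order 3, order-4 SSE and an
    order-5 match model, coding packed bytes bit by bit (MSB first)."""

    def __init__(self) -> None:
        self.m0 = BitContextModel()
        self.m1 = BitContextModel()
        self.m2 = BitContextModel()
        self.icm3 = BitHistoryModel()
        self.sse4 = SSE()
        self.match = MatchModel(order=5)
        self.mixer = Mixer(5)
        self.hist = 0           # last 4 bytes, little-endian in an int

    def code_byte(self, rc, byte=None) -> int:
        hist = self.hist
        h1 = hist & 0xFF
        h2 = hist & 0xFFFF
        h3 = hist & 0xFFFFFF
        h4 = hist & 0xFFFFFFFF
        part = 0
        for k in range(8):
            bitctx = (1 << k) | part
            k0 = bitctx
            k1 = _h32(1, h1, bitctx)
            k2 = _h32(2, h2, bitctx)
            k3 = _h32(3, h3, bitctx)
            k4 = _h32(4, h4, bitctx)
            p3 = self.icm3.predict(k3)
            p3r = self.sse4.refine(p3, k4)
            pm = self.match.predict_bit(part, k)
            p = self.mixer.mix(
                (self.m0.predict(k0), self.m1.predict(k1),
                 self.m2.predict(k2), p3r, pm), bitctx & 0xFF)
            if byte is None:
                bit = rc.decode_bit(p)
            else:
                bit = (byte >> (7 - k)) & 1
                rc.encode_bit(bit, p)
            self.mixer.update(bit)
            self.m0.update(k0, bit)
            self.m1.update(k1, bit)
            self.m2.update(k2, bit)
            self.icm3.update(k3, bit)
            self.sse4.update(bit)
            self.match.update_bit(bit)
            part = (part << 1) | bit
        value = part & 0xFF
        self.match.push_byte(value)
        self.hist = ((hist << 8) | value) & 0xFFFFFFFFFF
        return value


class FastqzSeqEncoder:
    """Packs reads and (in slow mode) codes the packed bytes with the
    six-model stack; fast mode stores the packed bytes raw."""

    def __init__(self, slow: bool = False) -> None:
        self.slow = slow
        self._raw = bytearray()
        self._rc = RangeEncoder() if slow else None
        self._stack = _SeqStack() if slow else None

    def add(self, seq: str) -> None:
        pb = pack_bases(seq)
        if self.slow:
            for b in pb.data:
                self._stack.code_byte(self._rc, b)
        else:
            self._raw += pb.data

    def finish(self) -> bytes:
        return self._rc.flush() if self.slow else bytes(self._raw)


class FastqzSeqDecoder:
    """Streaming inverse of :class:`FastqzSeqEncoder` (needs read lengths)."""

    def __init__(self, data: bytes, slow: bool = False) -> None:
        self.slow = slow
        self._data = data
        self._pos = 0
        self._rc = RangeDecoder(data) if slow else None
        self._stack = _SeqStack() if slow else None

    def get(self, length: int) -> str:
        got = 0
        codes = bytearray()
        while got < length:
            if self.slow:
                v = self._stack.code_byte(self._rc)
            else:
                v = self._data[self._pos]
                self._pos += 1
            codes.append(v)
            got += len(_decode_group(v)) if v >= 21 else (2 if v >= 5 else 1)
        return unpack_bases(PackedBases(bytes(codes), length))


def fastqz_seq_model_stack(packed: bytes) -> bytes:
    """Compress a packed-byte stream with the six-model stack."""
    rc = RangeEncoder()
    stack = _SeqStack()
    for b in packed:
        stack.code_byte(rc, b)
    return rc.flush()


def fastqz_seq_model_unstack(data: bytes, n_bytes: int) -> bytes:
    """Inverse of :func:`fastqz_seq_model_stack`."""
    if n_bytes == 0:
        return b""
    rc = RangeDecoder(data)
    stack = _SeqStack()
    return bytes(stack.code_byte(rc) for _ in range(n_bytes))
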