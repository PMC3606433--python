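"""SAM-based reference compression (samcomp).

Two schemes share the same side-stream machinery (identifiers coded as in
the fqzcomp tokenizer, qualities as in the fqzcomp quality coder, flags /
positions / mapping qualities / CIGARs in a fields stream):

* **samcomp1** requires position-sorted input.  Every called base is
  anchored to a reference coordinate through the SAM flags, position and
  CIGAR, and coded under a per-coordinate adaptive model.  As coverage
  accumulates each coordinate's model converges on the local consensus,
  so deep data compresses almost as well as with a reference.  A supplied
  reference seeds the initial model counts; without one, new models are
  seeded from a low-order consensus context learned on the fly.

* **samcomp2** accepts records in any order and keeps no per-coordinate
  state: each base is compared against the reference and a match bit is
  coded under a register of recent match outcomes; mismatching bases are
  coded with the reference base as context.  It needs a reference to be
  useful (a consensus-free fallback with a warning codes everything like
  unmapped data).

Only the columns qname, flag, rname, pos, mapq, cigar, seq and qual are
preserved; the header is carried verbatim as an opaque block and columns
7-9 are normalised to "*", "0", "0" as in the evaluation protocol of the
original tools.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .coder import BitContextModel, DirectContextModel, RangeDecoder, RangeEncoder
from .id_codec import IdDecoder, IdEncoder
from .qual_codec import FqzQualDecoder, FqzQualEncoder, QualitySymbols, canonicalize, decanonicalize

__all__ = [
    "SamRecordLite", "AnchoredBase", "PerPositionModel",
    "parse_cigar", "cigar_read_len", "anchor_bases",
    "SamEncoder", "SamDecoder", "samcomp1_encode", "samcomp2_encode",
    "sam_decode", "read_sam", "write_sam",
]

MATCHED, INSERTION, SOFTCLIP = 0, 1, 2

_BASE_SYM = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}
_SYM_BASE = "ACGT"
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# per-position model constants: fast adaptation suits consensus-style data
_PP_INC = 32
_PP_LIMIT = 224
_REF_SEED = 16


@dataclass
class SamRecordLite:
    """The retained subset of a SAM alignment line."""
    qname: str
    flag: int
    rname: str
    pos: int          # 1-based leftmost mapping position (0 if unmapped)
    mapq: int
    cigar: str
    seq: str
    qual: str

    @property
    def mapped(self) -> bool:
        return not (self.flag & 0x4) and self.rname != "*" and \
            self.cigar != "*" and self.pos > 0


@dataclass
class AnchoredBase:
    """One called base tied (or not) to a reference coordinate."""
    ref_coord: int | None
    base: str
    channel: int      # MATCHED / INSERTION / SOFTCLIP


def parse_cigar(cigar: str) -> list:
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return [(o, int(n)) for n, o in ops]


def cigar_read_len(cigar: str) -> int:
    return sum(n for o, n in parse_cigar(cigar) if o in "MIS=X")


def anchor_bases(rec: SamRecordLite) -> list:
    """Anchor each called base of a mapped record to a reference coordinate.

    M/=/X consume read and reference, I emits INSERTION bases, S emits
    SOFTCLIP bases, D/N advance the reference only and H consumes nothing.
    The first MATCHED coordinate is ``pos - 1`` (0-based).
    """
    if not rec.mapped:
        raise ValueError(f"record {rec.qname!r} is not mapped")
    ops = parse_cigar(rec.cigar)
    consumed = sum(n for o, n in ops if o in "MIS=X")
    if consumed != len(rec.seq):
        raise ValueError(
            f"record {rec.qname!r}: CIGAR consumes {consumed} bases but "
            f"SEQ has {len(rec.seq)}")
    out = []
    rpos = rec.pos - 1
    i = 0
    for op, n in ops:
        if op in "M=X":
            for _ in range(n):
                out.append(AnchoredBase(rpos, rec.seq[i], MATCHED))
                rpos += 1
                i += 1
        elif op == "I":
            for _ in range(n):
                out.append(AnchoredBase(None, rec.seq[i], INSERTION))
                i += 1
        elif op == "S":
            for _ in range(n):
                out.append(AnchoredBase(None, rec.seq[i], SOFTCLIP))
                i += 1
        elif op in "DN":
            rpos += n
        # H and P consume nothing we store
    return out


class PerPositionModel:
    """Reference-coordinate -> adaptive 4-symbol counters.

    Models are created on first touch.  With a reference the reference
    base gets an initial count advantage; otherwise the seed comes from a
    low-order consensus context (counts of first-touch observations keyed
    by the consensus call at the previous coordinate).
    """

    def __init__(self, ref_codes=None) -> None:
        self.models: dict = {}
        self.ref_codes = ref_codes           # list of 0..3/None or None
        self.seed_stats = {b: [0, 0, 0, 0] for b in range(5)}

    def _prev_consensus(self, coord: int) -> int:
        m = self.models.get(coord - 1)
        if m is None:
            return 4
        mx = max(m)
        return m.index(mx) if mx > 0 else 4

    def get(self, coord: int) -> list:
        m = self.models.get(coord)
        if m is not None:
            return m
        if self.ref_codes is not None and 0 <= coord < len(self.ref_codes):
            rb = self.ref_codes[coord]
            m = [0, 0, 0, 0]
            if rb is not None:
                m[rb] = _REF_SEED
        else:
            # seed from the consensus context only once it is informative;
            # an uninformative (near-uniform) seed would dilute the model
            pb = self._prev_consensus(coord)
            st = self.seed_stats[pb]
            tot = sum(st)
            m = [0, 0, 0, 0]
            if tot >= 16 and max(st) * 100 >= 55 * tot:
                m = [(st[i] * 8) // tot for i in range(4)]
        self.models[coord] = m
        return m

    def first_touch(self, coord: int, sym: int) -> None:
        """Record a first observation for the consensus-context stats."""
        self.seed_stats[self._prev_consensus(coord)][sym] += 1


def _zigzag(v: int) -> int:
    return (v << 1) ^ (v >> 63) if v < 0 else v << 1


def _unzigzag(u: int) -> int:
    return -(u >> 1) - 1 if u & 1 else u >> 1


class _FieldModels:
    """Models for the flags/rname/pos/mapq/cigar/len side stream."""

    def __init__(self) -> None:
        self.flag = [DirectContextModel(256) for _ in range(2)]
        self.same_rname = DirectContextModel(2)
        self.rname_idx = [DirectContextModel(256) for _ in range(2)]
        self.pos = [DirectContextModel(256) for _ in range(5)]
        self.mapq = DirectContextModel(256)
        self.cigar = DirectContextModel(96)
        self.length = [DirectContextModel(256) for _ in range(5)]
        self.has_seq = DirectContextModel(2)
        self.has_qual = DirectContextModel(2)


def _encode_varint(enc, models, u: int) -> None:
    for i in range(len(models)):
        b = u & 0x7F
        u >>= 7
        if u:
            models[i].encode(enc, 0, b | 0x80)
        else:
            models[i].encode(enc, 0, b)
            return
    raise ValueError("varint overflow")


def _decode_varint(dec, models) -> int:
    u = 0
    for i in range(len(models)):
        b = models[i].decode(dec, 0)
        u |= (b & 0x7F) << (7 * i)
        if not b & 0x80:
            return u
    raise ValueError("varint overflow")


_CIG_TERM = 95


def _encode_str(enc, model, s: str) -> None:
    prev = 0
    for ch in s:
        sym = ord(ch) - 32
        model.encode(enc, prev, sym)
        prev = sym
    model.encode(enc, prev, _CIG_TERM)


def _decode_str(dec, model) -> str:
    out = []
    prev = 0
    while True:
        sym = model.decode(dec, prev)
        if sym == _CIG_TERM:
            return "".join(out)
        out.append(chr(sym + 32))
        prev = sym


class _SmallSeqModels:
    """Order-2 insertion/softclip models and an order-8 unmapped model."""

    def __init__(self) -> None:
        self.ins: dict = {}
        self.clip: dict = {}
        self.unmapped: dict = {}


def _dcm4_encode(enc, table, key, sym, inc=8, limit=247):
    f = table.get(key)
    if f is None:
        f = [0, 0, 0, 0]
        table[key] = f
    cum = sym
    for i in range(sym):
        cum += f[i]
    enc.encode_freq(cum, f[sym] + 1, f[0] + f[1] + f[2] + f[3] + 4)
    f[sym] += inc
    if f[sym] > limit:
        f[0] = (f[0] + 1) >> 1
        f[1] = (f[1] + 1) >> 1
        f[2] = (f[2] + 1) >> 1
        f[3] = (f[3] + 1) >> 1


def _dcm4_decode(dec, table, key, inc=8, limit=247):
    f = table.get(key)
    if f is None:
        f = [0, 0, 0, 0]
        table[key] = f
    tot = f[0] + f[1] + f[2] + f[3] + 4
    target = dec.decode_target(tot)
    cum = 0
    for s in range(4):
        nxt = cum + f[s] + 1
        if target < nxt:
            break
        cum = nxt
    dec.decode_update(cum, f[s] + 1)
    f[s] += inc
    if f[s] > limit:
        f[0] = (f[0] + 1) >> 1
        f[1] = (f[1] + 1) >> 1
        f[2] = (f[2] + 1) >> 1
        f[3] = (f[3] + 1) >> 1
    return s


def _ref_to_codes(seq: str) -> list:
    return [_BASE_SYM.get(c) if c in "ACGT" else None for c in seq]


class SamEncoder:
    """Streaming samcomp encoder; mode is ``samcomp1`` or ``samcomp2``."""

    def __init__(self, mode: str = "samcomp1", ref: dict | None = None) -> None:
        if mode not in ("samcomp1", "samcomp2"):
            raise ValueError(f"unknown samcodec mode {mode!r}")
        self.mode = mode
        self.ref = ref or {}
        if mode == "samcomp2" and not self.ref:
            warnings.warn("samcomp2 without a reference compresses very "
                          "poorly; falling back to reference-free coding")
        self.id_enc = IdEncoder("tokenized")
        self.fld_enc = RangeEncoder()
        self.fld = _FieldModels()
        self.seq_enc = RangeEncoder()
        self.qual_enc = FqzQualEncoder(level=2)
        self.small = _SmallSeqModels()
        self.names: list = []
        self._name_idx: dict = {}
        self._prev_name = None
        self._prev_pos = 0
        self._done_names: set = set()
        self.exceptions: dict = {}
        self.n_records = 0
        self.covered: set = set()
        # samcomp1 state
        self.pp: PerPositionModel | None = None
        self._cur_ref_codes = None
        # samcomp2 state
        self.match_bit = BitContextModel(rate=4)
        self.mismatch = {}            # ref base code (0..4) -> counters
        self._hist = 0

    # -- helpers --------------------------------------------------------
    def _switch_rname(self, rname: str) -> None:
        if rname == self._prev_name:
            return
        if rname != "*":
            if self.mode == "samcomp1":
                last = getattr(self, "_last_mapped", None)
                if rname != last:
                    if rname in self._done_names:
                        raise ValueError(
                            f"input not position sorted: {rname} seen again")
                    if last is not None:
                        self._done_names.add(last)
                    self._last_mapped = rname
                    codes = None
                    if self.ref:
                        if rname not in self.ref:
                            raise ValueError(
                                f"reference has no sequence {rname!r}")
                        codes = _ref_to_codes(self.ref[rname])
                    self.pp = PerPositionModel(codes)
            if self.mode == "samcomp2":
                if self.ref:
                    if rname not in self.ref:
                        raise ValueError(
                            f"reference has no sequence {rname!r}")
                    cache = getattr(self, "_code_cache", None)
                    if cache is None:
                        cache = self._code_cache = {}
                    if rname not in cache:
                        cache[rname] = _ref_to_codes(self.ref[rname])
                    self._cur_ref_codes = cache[rname]
                else:
                    self._cur_ref_codes = None
        self._prev_name = rname
        self._prev_pos = 0

    def _encode_fields(self, rec: SamRecordLite) -> None:
        enc, fld = self.fld_enc, self.fld
        fld.flag[0].encode(enc, 0, rec.flag & 0xFF)
        fld.flag[1].encode(enc, 0, (rec.flag >> 8) & 0xFF)
        same = rec.rname == self._prev_name
        fld.same_rname.encode(enc, 0, 1 if same else 0)
        if not same:
            idx = self._name_idx.get(rec.rname)
            if idx is None:
                idx = len(self.names)
                self._name_idx[rec.rname] = idx
                self.names.append(rec.rname)
            fld.rname_idx[0].encode(enc, 0, idx & 0xFF)
            fld.rname_idx[1].encode(enc, 0, (idx >> 8) & 0xFF)
        base = self._prev_pos if same else 0
        _encode_varint(enc, fld.pos, _zigzag(rec.pos - base))
        fld.mapq.encode(enc, 0, rec.mapq & 0xFF)
        _encode_str(enc, fld.cigar, rec.cigar)
        if rec.cigar == "*":
            L = len(rec.seq) if rec.seq != "*" else \
                (len(rec.qual) if rec.qual != "*" else 0)
            _encode_varint(enc, fld.length, L)
        fld.has_seq.encode(enc, 0, 0 if rec.seq == "*" else 1)
        fld.has_qual.encode(enc, 0, 0 if rec.qual == "*" else 1)

    def _encode_seq_samcomp1(self, rec: SamRecordLite) -> None:
        enc = self.seq_enc
        small = self.small
        if not rec.mapped:
            ctx = 0
            for ch in rec.seq:
                s = _BASE_SYM[ch]
                _dcm4_encode(enc, small.unmapped, ctx, s)
                ctx = ((ctx << 2) | s) & 0xFFFF
            return
        pp = self.pp
        models = pp.models
        rpos = rec.pos - 1
        i = 0
        seq = rec.seq
        ictx = 0
        cctx = 0
        name = rec.rname
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                for _ in range(n):
                    s = _BASE_SYM[seq[i]]
                    f = models.get(rpos)
                    created = f is None
                    if created:
                        f = pp.get(rpos)
                    cum = s
                    for z in range(s):
                        cum += f[z]
                    enc.encode_freq(cum, f[s] + 1,
                                    f[0] + f[1] + f[2] + f[3] + 4)
                    if created and pp.ref_codes is None:
                        pp.seed_stats[pp._prev_consensus(rpos)][s] += 1
                    f[s] += _PP_INC
                    if f[s] > _PP_LIMIT:
                        f[0] = (f[0] + 1) >> 1
                        f[1] = (f[1] + 1) >> 1
                        f[2] = (f[2] + 1) >> 1
                        f[3] = (f[3] + 1) >> 1
                    self.covered.add((name, rpos))
                    rpos += 1
                    i += 1
            elif op == "I":
                for _ in range(n):
                    s = _BASE_SYM[seq[i]]
                    _dcm4_encode(enc, small.ins, ictx, s)
                    ictx = ((ictx << 2) | s) & 0xF
                    i += 1
            elif op == "S":
                for _ in range(n):
                    s = _BASE_SYM[seq[i]]
                    _dcm4_encode(enc, small.clip, cctx, s)
                    cctx = ((cctx << 2) | s) & 0xF
                    i += 1
            elif op in "DN":
                rpos += n

    def _encode_seq_samcomp2(self, rec: SamRecordLite) -> None:
        enc = self.seq_enc
        small = self.small
        refc = self._cur_ref_codes
        if not rec.mapped or refc is None:
            ctx = 0
            for ch in rec.seq:
                s = _BASE_SYM[ch]
                _dcm4_encode(enc, small.unmapped, ctx, s)
                ctx = ((ctx << 2) | s) & 0xFFFF
            return
        rpos = rec.pos - 1
        i = 0
        seq = rec.seq
        ictx = 0
        cctx = 0
        hist = self._hist
        mb = self.match_bit
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                for _ in range(n):
                    s = _BASE_SYM[seq[i]]
                    rb = refc[rpos] if 0 <= rpos < len(refc) else None
                    rbk = 4 if rb is None else rb
                    match = 1 if rb == s else 0
                    p = mb.predict(hist)
                    enc.encode_bit(match, p)
                    mb.update(hist, match)
                    hist = ((hist << 1) | match) & 0xFFFF
                    if not match:
                        # code the base under the reference-base context,
                        # excluding the known-mismatching symbol is not
                        # possible when rb is None
                        _dcm4_encode(enc, self.mismatch, rbk, s)
                    rpos += 1
                    i += 1
            elif op == "I":
                for _ in range(n):
                    s = _BASE_SYM[seq[i]]
                    _dcm4_encode(enc, small.ins, ictx, s)
                    ictx = ((ictx << 2) | s) & 0xF
                    i += 1
            elif op == "S":
                for _ in range(n):
                    s = _BASE_SYM[seq[i]]
                    _dcm4_encode(enc, small.clip, cctx, s)
                    cctx = ((cctx << 2) | s) & 0xF
                    i += 1
            elif op in "DN":
                rpos += n
        self._hist = hist

    def add(self, rec: SamRecordLite) -> None:
        if rec.mapped:
            consumed = cigar_read_len(rec.cigar)
            if rec.seq != "*" and consumed != len(rec.seq):
                raise ValueError(
                    f"record {rec.qname!r}: CIGAR/SEQ length mismatch")
        if self.mode == "samcomp1" and rec.mapped and \
                rec.rname == self._prev_name and rec.pos < self._prev_pos:
            raise ValueError(
                f"input not position sorted at record {rec.qname!r}")
        if rec.cigar != "*" and rec.seq != "*" and \
                cigar_read_len(rec.cigar) != len(rec.seq):
            raise ValueError(
                f"record {rec.qname!r}: CIGAR/SEQ length mismatch")
        self.id_enc.add(rec.qname)
        self._encode_fields(rec)
        self._switch_rname(rec.rname)
        idx = self.n_records
        seq = rec.seq if rec.seq != "*" else ""
        if any(c not in "ACGTN" for c in seq):
            raise ValueError(
                f"record {rec.qname!r}: unsupported base in SEQ")
        # qualities (with exception tracking for exact round-tripping)
        if rec.qual != "*":
            seq_for_n = seq if seq else "A" * len(rec.qual)
            qs = canonicalize(rec.qual, seq_for_n)
            self.qual_enc.add(qs)
            recon = decanonicalize(qs)
            exc_q = [[p, ord(c)] for p, (c, r)
                     in enumerate(zip(rec.qual, recon)) if c != r]
            n_from_q = {p for p, c in enumerate(recon) if c == "!"}
        else:
            exc_q = []
            n_from_q = set()
        n_actual = {p for p, c in enumerate(seq) if c == "N"}
        exc_s = sorted(n_from_q.symmetric_difference(n_actual))
        exc_s = [[p, seq[p] if p < len(seq) else "A"] for p in exc_s
                 if p < len(seq)]
        if exc_q or exc_s:
            self.exceptions[str(idx)] = {"q": exc_q, "s": exc_s}
        if seq:
            if self.mode == "samcomp1":
                self._encode_seq_samcomp1(rec)
            else:
                self._encode_seq_samcomp2(rec)
        if rec.mapped:
            self._prev_pos = rec.pos
        self.n_records += 1

    def finish(self) -> dict:
        return {
            "ID": self.id_enc.finish(),
            "FLD": self.fld_enc.flush(),
            "SEQ": self.seq_enc.flush(),
            "QUAL": self.qual_enc.finish(),
        }

    def meta(self) -> dict:
        return {
            "n_records": self.n_records,
            "names": self.names,
            "exceptions": self.exceptions,
        }


class SamDecoder:
    """Streaming inverse of :class:`SamEncoder`."""

    def __init__(self, blocks: dict, meta: dict, mode: str,
                 ref: dict | None = None) -> None:
        self.mode = mode
        self.ref = ref or {}
        self.meta = meta
        self.id_dec = IdDecoder(blocks["ID"], "tokenized")
        self.fld_dec = RangeDecoder(blocks["FLD"])
        self.fld = _FieldModels()
        self.seq_dec = RangeDecoder(blocks["SEQ"]) if blocks["SEQ"] else None
        self.qual_dec = FqzQualDecoder(blocks["QUAL"], level=2)
        self.small = _SmallSeqModels()
        self.names = meta["names"]
        self._prev_name = None
        self._prev_pos = 0
        self.pp: PerPositionModel | None = None
        self._cur_ref_codes = None
        self.match_bit = BitContextModel(rate=4)
        self.mismatch = {}
        self._hist = 0
        self._idx = 0

    def _switch_rname(self, rname: str) -> None:
        if rname == self._prev_name:
            return
        if rname != "*":
            if self.mode == "samcomp1":
                last = getattr(self, "_last_mapped", None)
                if rname != last:
                    self._last_mapped = rname
                    codes = None
                    if self.ref:
                        if rname not in self.ref:
                            raise ValueError(
                                f"reference has no sequence {rname!r}")
                        codes = _ref_to_codes(self.ref[rname])
                    self.pp = PerPositionModel(codes)
            if self.mode == "samcomp2":
                if self.ref:
                    cache = getattr(self, "_code_cache", None)
                    if cache is None:
                        cache = self._code_cache = {}
                    if rname not in cache:
                        cache[rname] = _ref_to_codes(self.ref[rname])
                    self._cur_ref_codes = cache[rname]
                else:
                    self._cur_ref_codes = None
        self._prev_name = rname
        self._prev_pos = 0

    def _decode_fields(self):
        dec, fld = self.fld_dec, self.fld
        flag = fld.flag[0].decode(dec, 0) | fld.flag[1].decode(dec, 0) << 8
        if fld.same_rname.decode(dec, 0):
            rname = self._prev_name
        else:
            idx = fld.rname_idx[0].decode(dec, 0) | \
                fld.rname_idx[1].decode(dec, 0) << 8
            rname = self.names[idx]
        # note: pos delta is relative to the previous pos of the same rname
        delta = _unzigzag(_decode_varint(dec, fld.pos))
        mapq = fld.mapq.decode(dec, 0)
        cigar = _decode_str(dec, fld.cigar)
        L = None
        if cigar == "*":
            L = _decode_varint(dec, fld.length)
        has_seq = fld.has_seq.decode(dec, 0)
        has_qual = fld.has_qual.decode(dec, 0)
        return flag, rname, delta, mapq, cigar, L, has_seq, has_qual

    def _decode_seq_samcomp1(self, rec, length: int) -> str:
        dec = self.seq_dec
        small = self.small
        out = []
        if not rec.mapped:
            ctx = 0
            for _ in range(length):
                s = _dcm4_decode(dec, small.unmapped, ctx)
                ctx = ((ctx << 2) | s) & 0xFFFF
                out.append(_SYM_BASE[s])
            return "".join(out)
        pp = self.pp
        models = pp.models
        rpos = rec.pos - 1
        ictx = 0
        cctx = 0
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                for _ in range(n):
                    f = models.get(rpos)
                    created = f is None
                    if created:
                        f = pp.get(rpos)
                    tot = f[0] + f[1] + f[2] + f[3] + 4
                    target = dec.decode_target(tot)
                    cum = 0
                    for s in range(4):
                        nxt = cum + f[s] + 1
                        if target < nxt:
                            break
                        cum = nxt
                    dec.decode_update(cum, f[s] + 1)
                    if created and pp.ref_codes is None:
                        pp.seed_stats[pp._prev_consensus(rpos)][s] += 1
                    f[s] += _PP_INC
                    if f[s] > _PP_LIMIT:
                        f[0] = (f[0] + 1) >> 1
                        f[1] = (f[1] + 1) >> 1
                        f[2] = (f[2] + 1) >> 1
                        f[3] = (f[3] + 1) >> 1
                    out.append(_SYM_BASE[s])
                    rpos += 1
            elif op == "I":
                for _ in range(n):
                    s = _dcm4_decode(dec, small.ins, ictx)
                    ictx = ((ictx << 2) | s) & 0xF
                    out.append(_SYM_BASE[s])
            elif op == "S":
                for _ in range(n):
                    s = _dcm4_decode(dec, small.clip, cctx)
                    cctx = ((cctx << 2) | s) & 0xF
                    out.append(_SYM_BASE[s])
            elif op in "DN":
                rpos += n
        return "".join(out)

    def _decode_seq_samcomp2(self, rec, length: int) -> str:
        dec = self.seq_dec
        small = self.small
        refc = self._cur_ref_codes
        out = []
        if not rec.mapped or refc is None:
            ctx = 0
            for _ in range(length):
                s = _dcm4_decode(dec, small.unmapped, ctx)
                ctx = ((ctx << 2) | s) & 0xFFFF
                out.append(_SYM_BASE[s])
            return "".join(out)
        rpos = rec.pos - 1
        ictx = 0
        cctx = 0
        hist = self._hist
        mb = self.match_bit
        for op, n in parse_cigar(rec.cigar):
            if op in "M=X":
                for _ in range(n):
                    rb = refc[rpos] if 0 <= rpos < len(refc) else None
                    rbk = 4 if rb is None else rb
                    p = mb.predict(hist)
                    match = dec.decode_bit(p)
                    mb.update(hist, match)
                    hist = ((hist << 1) | match) & 0xFFFF
                    if match:
                        s = rb if rb is not None else 0
                    else:
                        s = _dcm4_decode(dec, self.mismatch, rbk)
                    out.append(_SYM_BASE[s])
                    rpos += 1
            elif op == "I":
                for _ in range(n):
                    s = _dcm4_decode(dec, small.ins, ictx)
                    ictx = ((ictx << 2) | s) & 0xF
                    out.append(_SYM_BASE[s])
            elif op == "S":
                for _ in range(n):
                    s = _dcm4_decode(dec, small.clip, cctx)
                    cctx = ((cctx << 2) | s) & 0xF
                    out.append(_SYM_BASE[s])
            elif op in "DN":
                rpos += n
        self._hist = hist
        return "".join(out)

    def get(self) -> SamRecordLite:
        qname = self.id_dec.get()
        flag, rname, delta, mapq, cigar, L, has_seq, has_qual = \
            self._decode_fields()
        self._switch_rname(rname)
        pos = self._prev_pos + delta
        rec = SamRecordLite(qname, flag, rname, pos, mapq, cigar, "", "")
        if cigar != "*":
            L = cigar_read_len(cigar)
        if has_qual:
            qs = self.qual_dec.get(L)
            qual = decanonicalize(qs)
        else:
            qual = "*"
        if has_seq:
            if self.mode == "samcomp1":
                seq = self._decode_seq_samcomp1(rec, L)
            else:
                seq = self._decode_seq_samcomp2(rec, L)
            if qual != "*":
                seq = "".join(
                    "N" if q == "!" else b for b, q in zip(seq, qual))
        else:
            seq = "*"
        exc = self.meta.get("exceptions", {}).get(str(self._idx))
        if exc:
            if exc["q"] and qual != "*":
                ql = list(qual)
                for p, o in exc["q"]:
                    ql[p] = chr(o)
                qual = "".join(ql)
            if exc["s"] and seq != "*":
                sl = list(seq)
                for p, b in exc["s"]:
                    sl[p] = b
                seq = "".join(sl)
        rec.seq = seq
        rec.qual = qual
        if rec.mapped:
            self._prev_pos = pos
        self._idx += 1
        return rec


# ---------------------------------------------------------------------------
# convenience entry points
# ---------------------------------------------------------------------------

def samcomp1_encode(records, ref: dict | None = None,
                    header_text: str = "") -> bytes:
    """Compress position-sorted records to container bytes."""
    from .container_io import build_sam_container
    return build_sam_container(records, "samcomp1", ref, header_text)


def samcomp2_encode(records, ref: dict | None = None,
                    header_text: str = "") -> bytes:
    """Compress records (any order) against a reference to container bytes."""
    from .container_io import build_sam_container
    return build_sam_container(records, "samcomp2", ref, header_text)


def sam_decode(data: bytes, ref: dict | None = None):
    """Inverse of the two encoders: (header_text, records)."""
    from .container_io import read_sam_container
    return read_sam_container(data, ref)


# ---------------------------------------------------------------------------
# SAM text I/O via pysam
# ---------------------------------------------------------------------------

def read_sam(path: str):
    """Read a SAM text file; returns (header_text, list of SamRecordLite).

    Template columns 7-9 and auxiliary tags are normalised away, as in
    the comparison protocol the original tools were evaluated under.
    """
    import pysam
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        header_text = str(fh.header)
        records = []
        for aln in fh:
            records.append(SamRecordLite(
                qname=aln.query_name or "*",
                flag=aln.flag,
                rname=aln.reference_name if aln.reference_id >= 0 else "*",
                pos=aln.reference_start + 1 if aln.reference_start is not None
                    and aln.reference_id >= 0 else 0,
                mapq=aln.mapping_quality,
                cigar=aln.cigarstring or "*",
                seq=aln.query_sequence or "*",
                qual="*" if aln.query_qualities is None else
                     "".join(chr(q + 33) for q in aln.query_qualities),
            ))
    return header_text, records


def write_sam(path: str, header_text: str, records) -> None:
    """Write records as SAM text with the stored header."""
    with open(path, "w") as fh:
        if header_text:
            fh.write(header_text if header_text.endswith("\n")
                     else header_text + "\n")
        for r in records:
            fh.write("\t".join([
                r.qname, str(r.flag), r.rname, str(r.pos), str(r.mapq),
                r.cigar, "*", "0", "0", r.seq, r.qual]) + "\n")
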