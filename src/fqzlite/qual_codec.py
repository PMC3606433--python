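"""Quality-score compression.

Phred+33 quality strings are first mapped to canonical symbols 0..63:
ASCII minus 33, clamped to 62, with 0 reserved for 'N' base calls and 63
a sentinel replacing a terminal run (length >= 2) of score 2 — the
signature of the Illumina "read became unreliable" tail.

The fqzcomp path codes symbols under adaptive context models of three
strengths: the previous quality; the previous two (second quantised); and
additionally the read position, the maximum of a recent window and a
"read has gone bad" indicator — the three correlations quality streams
show (neighbour correlation, positional decline, good/bad reads).

The fastqz path packs symbols into byte codes (runs of 38, triples in
35..38, pairs in 31..38, singles, end-of-2s marker) and optionally codes
those bytes with a small context-mixing model.

Both lossy modes live here: ``fastqz_round`` (round to a multiple of Q)
and ``fqzcomp_within`` (choose the cheapest value within +-Q under the
current context model).
"""

from __future__ import annotations

from dataclasses import dataclass

from .coder import (
    BitContextModel, DirectContextModel, Mixer, RangeDecoder, RangeEncoder,
)

__all__ = [
    "QualitySymbols", "QualContextSpec", "LossyConfig",
    "canonicalize", "decanonicalize", "qual_context",
    "fastqz_pack_quals", "fastqz_unpack_quals", "lossy_map", "fastqz_round",
    "FqzQualEncoder", "FqzQualDecoder",
    "FastqzQualEncoder", "FastqzQualDecoder",
]

RUN2_SENTINEL = 63
MAX_Q = 62


@dataclass
class QualitySymbols:
    """Canonical quality symbols for one read."""
    symbols: list          # ints 0..63; 63 only as final element
    length: int            # original read length L


@dataclass
class QualContextSpec:
    """Which history features enter the context key (levels 1..3)."""
    level: int = 2

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ValueError("context level must be 1, 2 or 3")


@dataclass
class LossyConfig:
    """Quantisation factor Q and which lossy scheme applies (Q=1: lossless)."""
    Q: int = 1
    mode: str = "fqzcomp_within"     # or "fastqz_round"

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.mode not in ("fqzcomp_within", "fastqz_round"):
            raise ValueError(f"unknown lossy mode {self.mode!r}")


def canonicalize(qual_line: str, seq_line: str) -> QualitySymbols:
    """Map a Phred+33 quality line to canonical symbols.

    Raises on length mismatch or characters outside ASCII 33..126.
    Returns clamped symbols; callers needing byte-exactness must check the
    (q==0) <=> (base=='N') convention and q<=62 themselves (see
    :mod:`fqzlite.container_io`'s exception side-channel).
    """
    if len(qual_line) != len(seq_line):
        raise ValueError("quality and sequence lengths differ")
    syms = []
    for ch, base in zip(qual_line, seq_line):
        q = ord(ch) - 33
        if not 0 <= q <= 93:
            raise ValueError(f"quality character {ch!r} outside Phred+33 range")
        if base == "N":
            q = 0
        elif q == 0:
            q = 1          # 0 is reserved for N (enforced; see exceptions)
        elif q > MAX_Q:
            q = MAX_Q
        syms.append(q)
    # collapse a terminal run (>=2) of score 2 into the sentinel
    n2 = 0
    while n2 < len(syms) and syms[-1 - n2] == 2:
        n2 += 1
    if n2 >= 2:
        syms = syms[:len(syms) - n2] + [RUN2_SENTINEL]
    return QualitySymbols(syms, len(qual_line))


def decanonicalize(qs: QualitySymbols) -> str:
    """Inverse of :func:`canonicalize` (modulo clamping/enforcement)."""
    syms = qs.symbols
    if syms and syms[-1] == RUN2_SENTINEL:
        syms = syms[:-1] + [2] * (qs.length - len(syms) + 1)
    if len(syms) != qs.length:
        raise ValueError("symbol count inconsistent with read length")
    return "".join(chr(q + 33) for q in syms)


def qual_context(history, i: int, spec: QualContextSpec) -> int:
    """Pure context key for the quality at position ``i``.

    Level 1: previous quality.  Level 2: adds the quantised second-previous
    quality.  Level 3: adds a position bucket, the (quantised) maximum of
    the previous six qualities and an indicator that any quality so far
    was below 20 — the positional-decline and good/bad-read correlations.
    """
    q1 = history[i - 1] if i >= 1 else 0
    if spec.level == 1:
        return q1
    q2 = history[i - 2] if i >= 2 else 0
    if spec.level == 2:
        return q1 | (q2 // 4) << 6
    # level 3 quantises harder than level 2 so the extra positional and
    # read-state components do not dilute the per-context statistics
    pos = min(i, 127) // 16
    lo = i - 6 if i >= 6 else 0
    wmax = max(history[lo:i]) if i > lo else 0
    bad = 1 if any(q < 20 for q in history[:i]) else 0
    return q1 | (q2 // 8) << 6 | pos << 9 | (wmax // 8) << 12 | bad << 15


# ---------------------------------------------------------------------------
# fqzcomp quality coding
# ---------------------------------------------------------------------------

class FqzQualEncoder:
    """Adaptive context-model encoder for canonical quality symbols.

    With a lossy config (Q>1, mode ``fqzcomp_within``) every symbol above
    Q is replaced by the value within +-Q that the current context model
    predicts most strongly, i.e. the one that encodes to the fewest bits.
    """

    def __init__(self, level: int = 2, lossy: LossyConfig | None = None) -> None:
        self.spec = QualContextSpec(level)
        self.lossy = lossy or LossyConfig()
        self.model = DirectContextModel(64, inc=16)
        self.enc = RangeEncoder()

    def _lossy_pick(self, key: int, v: int) -> int:
        cfg = self.lossy
        if cfg.Q == 1 or v <= cfg.Q or v == RUN2_SENTINEL:
            return v
        if cfg.mode == "fastqz_round":
            return fastqz_round(v, cfg.Q)
        counts = self.model.counts(key)
        lo = max(1, v - cfg.Q)
        hi = min(MAX_Q, v + cfg.Q)
        best = v
        best_c = -1
        for cand in range(lo, hi + 1):
            c = counts[cand]
            # ties: prefer the value closest to the original, then smaller
            if c > best_c or (c == best_c and abs(cand - v) < abs(best - v)):
                best, best_c = cand, c
        return best

    def add(self, qs: QualitySymbols) -> list:
        """Encode one read's symbols; returns the symbols as stored."""
        spec, model, enc = self.spec, self.model, self.enc
        stored = []
        for i, v in enumerate(qs.symbols):
            key = qual_context(stored, i, spec)
            v = self._lossy_pick(key, v)
            stored.append(v)
            model.encode(enc, key, v)
        return stored

    def finish(self) -> bytes:
        return self.enc.flush()


class FqzQualDecoder:
    """Streaming inverse of :class:`FqzQualEncoder`."""

    def __init__(self, data: bytes, level: int = 2) -> None:
        self.spec = QualContextSpec(level)
        self.model = DirectContextModel(64, inc=16)
        self.dec = RangeDecoder(data)

    def get(self, length: int) -> QualitySymbols:
        spec, model, dec = self.spec, self.model, self.dec
        syms: list = []
        for i in range(length):
            v = model.decode(dec, qual_context(syms, i, spec))
            syms.append(v)
            if v == RUN2_SENTINEL:
                break
        return QualitySymbols(syms, length)


def lossy_map(symbols, cfg: LossyConfig, model_state=None) -> list:
    """Apply a lossy quantisation to canonical symbols (0/N and sentinel
    handling unchanged).

    For ``fqzcomp_within`` a live model state (a
    :class:`~fqzlite.coder.DirectContextModel` keyed like the encoder's)
    may be supplied; without one the original value is kept when all
    candidates are equally cheap, which mirrors an untrained model.
    """
    if cfg.Q == 1:
        return list(symbols)
    out = []
    model = model_state if model_state is not None else DirectContextModel(64)
    spec = QualContextSpec(2)
    for i, v in enumerate(symbols):
        if v <= cfg.Q or v == RUN2_SENTINEL:
            out.append(v)
            continue
        if cfg.mode == "fastqz_round":
            out.append(fastqz_round(v, cfg.Q))
            continue
        key = qual_context(out, i, spec)
        counts = model.counts(key)
        lo, hi = max(1, v - cfg.Q), min(MAX_Q, v + cfg.Q)
        best, best_c = v, counts[v]
        for cand in range(lo, hi + 1):
            c = counts[cand]
            if c > best_c or (c == best_c and abs(cand - v) < abs(best - v)):
                best, best_c = cand, c
        out.append(best)
        model.update(key, best)
    return out


def fastqz_round(v: int, Q: int) -> int:
    """Round a quality value above 1 to a multiple of Q (0 stays reserved)."""
    if v <= 1 or Q == 1:
        return v
    r = Q * ((2 * v + Q) // (2 * Q))       # round half up
    if r == 0:
        r = 1
    elif r > MAX_Q:
        r = MAX_Q
    return r


# ---------------------------------------------------------------------------
# fastqz byte-code packing
# ---------------------------------------------------------------------------
# code layout (counts from the scheme: 55 runs + 64 triples + 64 pairs +
# 63 singles + 1 marker = 247 <= 256):
#   0          : rest-of-read is score 2 (also stands for the sentinel 63)
#   1 .. 55    : run of score 38, length = code
#   56 .. 119  : triple (a,b,c), each in 35..38: 56 + (a-35)*16+(b-35)*4+(c-35)
#   120 .. 183 : pair (a,b), each in 31..38:   120 + (a-31)*8+(b-31)
#   184 .. 246 : single score s in 0..62:      184 + s

_RUN_MAX = 55
_TRIPLE0, _PAIR0, _SINGLE0, _MARKER = 56, 120, 184, 0


def fastqz_pack_quals(qs: QualitySymbols) -> bytes:
    """Greedy left-to-right packing: run > triple > pair > single."""
    syms = qs.symbols
    out = bytearray()
    i, n = 0, len(syms)
    while i < n:
        v = syms[i]
        if v == RUN2_SENTINEL:
            out.append(_MARKER)
            i += 1
            continue
        if v == 38:
            j = i
            while j < n and syms[j] == 38 and j - i < _RUN_MAX:
                j += 1
            out.append(j - i)
            i = j
            continue
        if i + 2 < n and all(35 <= syms[i + k] <= 38 and
                             syms[i + k] != RUN2_SENTINEL for k in range(3)):
            a, b, c = syms[i], syms[i + 1], syms[i + 2]
            out.append(_TRIPLE0 + (a - 35) * 16 + (b - 35) * 4 + (c - 35))
            i += 3
            continue
        if i + 1 < n and 31 <= v <= 38 and 31 <= syms[i + 1] <= 38:
            out.append(_PAIR0 + (v - 31) * 8 + (syms[i + 1] - 31))
            i += 2
            continue
        out.append(_SINGLE0 + v)
        i += 1
    return bytes(out)


def fastqz_unpack_quals(codes, length: int) -> QualitySymbols:
    """Inverse of :func:`fastqz_pack_quals` given the read length."""
    syms: list = []
    for code in codes:
        if code == _MARKER:
            syms.append(RUN2_SENTINEL)
            break
        if 1 <= code <= _RUN_MAX:
            syms.extend([38] * code)
        elif code < _PAIR0:
            c = code - _TRIPLE0
            syms.extend([35 + (c >> 4), 35 + ((c >> 2) & 3), 35 + (c & 3)])
        elif code < _SINGLE0:
            c = code - _PAIR0
            syms.extend([31 + (c >> 3), 31 + (c & 7)])
        else:
            syms.append(code - _SINGLE0)
        if len(syms) >= length:
            break
    return QualitySymbols(syms, length)


class FastqzQualEncoder:
    """fastqz quality path: pack to byte codes; slow mode context-models them.

    Slow-mode models: three direct bit models over (previous code), the
    (previous two codes) and (position-in-read bucket, previous code), all
    hashed with the partial bits of the current byte and mixed with weights
    selected by the previous code's high bits.  A per-read terminator code
    247 delimits reads in the byte stream.
    """

    TERM = 247

    def __init__(self, slow: bool = False,
                 lossy: LossyConfig | None = None) -> None:
        self.slow = slow
        self.lossy = lossy or LossyConfig()
        self._raw = bytearray()
        if slow:
            self._rc = RangeEncoder()
            self.m1 = BitContextModel()
            self.m2 = BitContextModel()
            self.m3 = BitContextModel()
            self.mixer = Mixer(3)
            self._hist = [0, 0]
            self._pos = 0

    def _code_byte(self, byte: int) -> None:
        h1, h2 = self._hist
        posb = min(self._pos, 63) >> 2
        bitctx = 1
        for k in range(8):
            k1 = h1 << 8 | bitctx
            k2 = (h1 << 16 | h2 << 8 | bitctx) ^ 0x5A0000
            k3 = (posb << 20 | h1 << 8 | bitctx) ^ 0xA50000
            p = self.mixer.mix((self.m1.predict(k1), self.m2.predict(k2),
                                self.m3.predict(k3)), h1 >> 3)
            bit = (byte >> (7 - k)) & 1
            self._rc.encode_bit(bit, p)
            self.mixer.update(bit)
            self.m1.update(k1, bit)
            self.m2.update(k2, bit)
            self.m3.update(k3, bit)
            bitctx = (bitctx << 1) | bit
        self._hist = [byte, h1]
        self._pos += 1

    def add(self, qs: QualitySymbols) -> list:
        if self.lossy.Q > 1:
            stored = lossy_map(qs.symbols, self.lossy)
            qs = QualitySymbols(stored, qs.length)
        codes = fastqz_pack_quals(qs) + bytes([self.TERM])
        if self.slow:
            self._pos = 0
            for b in codes:
                self._code_byte(b)
        else:
            self._raw += codes
        return list(qs.symbols)

    def finish(self) -> bytes:
        return self._rc.flush() if self.slow else bytes(self._raw)


class FastqzQualDecoder:
    """Streaming inverse of :class:`FastqzQualEncoder`."""

    def __init__(self, data: bytes, slow: bool = False) -> None:
        self.slow = slow
        if slow:
            self._rc = RangeDecoder(data)
            self.m1 = BitContextModel()
            self.m2 = BitContextModel()
            self.m3 = BitContextModel()
            self.mixer = Mixer(3)
            self._hist = [0, 0]
            self._pos = 0
        else:
            self._data = data
            self._ofs = 0

    def _decode_byte(self) -> int:
        h1, h2 = self._hist
        posb = min(self._pos, 63) >> 2
        bitctx = 1
        for _ in range(8):
            k1 = h1 << 8 | bitctx
            k2 = (h1 << 16 | h2 << 8 | bitctx) ^ 0x5A0000
            k3 = (posb << 20 | h1 << 8 | bitctx) ^ 0xA50000
            p = self.mixer.mix((self.m1.predict(k1), self.m2.predict(k2),
                                self.m3.predict(k3)), h1 >> 3)
            bit = self._rc.decode_bit(p)
            self.mixer.update(bit)
            self.m1.update(k1, bit)
            self.m2.update(k2, bit)
            self.m3.update(k3, bit)
            bitctx = (bitctx << 1) | bit
        byte = bitctx & 0xFF
        self._hist = [byte, h1]
        self._pos += 1
        return byte

    def get(self, length: int) -> QualitySymbols:
        codes = bytearray()
        if self.slow:
            self._pos = 0
            while True:
                b = self._decode_byte()
                if b == FastqzQualEncoder.TERM:
                    break
                codes.append(b)
        else:
            while True:
                b = self._data[self._ofs]
                self._ofs += 1
                if b == FastqzQualEncoder.TERM:
                    break
                codes.append(b)
        return fastqz_unpack_quals(codes, length)
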