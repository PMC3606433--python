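"""Sequence-identifier compression.

Two families of identifier coding are provided:

* **fqzcomp-style tokenization**: each identifier is split into
  ``{type, value}`` tokens (alpha runs, numeric runs, leading-zero runs,
  punctuation runs) and coded against the previous identifier's tokens —
  identical tokens become MATCH, small numeric increases become DELTA, and
  everything is coded under per-slot adaptive models.  A simple
  string-delta mode (common-prefix length + literal suffix) is also
  available and works better on 454-style base-64 names.

* **fastqz-style line deltas**: the current line is expressed as
  "go to column c, add `inc` to the decimal string there, copy the first
  `match_len` bytes of the adjusted previous line, then append a literal"
  — a single byte-code record per identifier, optionally context-model
  coded in slow mode.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .coder import (
    BitContextModel, BitHistoryModel, DirectContextModel, Mixer,
    RangeDecoder, RangeEncoder,
)

__all__ = [
    "IdToken", "LineDelta",
    "ALPHA", "NUMERIC", "LEADING_ZERO_NUMERIC", "PUNCT", "MATCH", "DELTA",
    "tokenize_id", "detokenize", "diff_tokens",
    "encode_id_stream", "decode_id_stream",
    "fastqz_delta", "apply_line_delta",
    "FastqzIdEncoder", "FastqzIdDecoder",
]

# token types
ALPHA = 0
NUMERIC = 1
LEADING_ZERO_NUMERIC = 2
PUNCT = 3
MATCH = 4
DELTA = 5
_END = 6          # internal stream terminator type

_TYPE_NAMES = {ALPHA: "ALPHA", NUMERIC: "NUMERIC",
               LEADING_ZERO_NUMERIC: "LEADING_ZERO_NUMERIC",
               PUNCT: "PUNCT", MATCH: "MATCH", DELTA: "DELTA"}

MAX_TOKENS = 32   # identifiers splitting into more fall back to string delta


@dataclass
class IdToken:
    """One ``{type, value}`` identifier token; ``slot`` is its 1-based ordinal."""
    type: int
    value: object     # str for ALPHA/PUNCT, int for NUMERIC/DELTA/zero-run
    slot: int = 0

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"IdToken({_TYPE_NAMES.get(self.type, self.type)}, {self.value!r}, slot={self.slot})"


_RUN_RE = re.compile(r"[A-Za-z]+|[0-9]+|[^A-Za-z0-9]+")
_RUN_RE_ALNUM = re.compile(r"[A-Za-z][A-Za-z0-9]*|[0-9]+|[^A-Za-z0-9]+")


def tokenize_id(identifier: str, alnum: bool = False) -> list:
    """Split an identifier into maximal-munch typed tokens.

    Digit runs with a leading '0' yield a LEADING_ZERO_NUMERIC token
    holding the zero-run length, followed (if digits remain) by a NUMERIC
    token; other digit runs are NUMERIC; letter runs ALPHA; everything
    else a single PUNCT token per run.  With ``alnum=True`` a letter
    followed by letters/digits forms one ALPHA token (helps 454 names).
    """
    tokens: list = []
    rx = _RUN_RE_ALNUM if alnum else _RUN_RE
    for mo in rx.finditer(identifier):
        run = mo.group(0)
        c = run[0]
        if c.isdigit():
            if c == "0":
                nz = len(run) - len(run.lstrip("0"))
                tokens.append(IdToken(LEADING_ZERO_NUMERIC, nz))
                rest = run[nz:]
                if rest:
                    tokens.append(IdToken(NUMERIC, int(rest)))
            else:
                tokens.append(IdToken(NUMERIC, int(run)))
        elif c.isalpha():
            tokens.append(IdToken(ALPHA, run))
        else:
            tokens.append(IdToken(PUNCT, run))
    for i, t in enumerate(tokens):
        t.slot = i + 1
    return tokens


def detokenize(tokens) -> str:
    """Inverse of :func:`tokenize_id` (byte-for-byte)."""
    parts = []
    for t in tokens:
        if t.type in (ALPHA, PUNCT):
            parts.append(t.value)
        elif t.type == NUMERIC:
            parts.append(str(t.value))
        elif t.type == LEADING_ZERO_NUMERIC:
            parts.append("0" * t.value)
        else:
            raise ValueError("detokenize expects literal tokens only")
    return "".join(parts)


def diff_tokens(prev, cur) -> list:
    """Re-express ``cur`` tokens relative to ``prev`` (same-slot compare).

    Identical type+value becomes MATCH; NUMERIC pairs whose value grew by
    0..255 become DELTA(difference); anything else keeps the literal token.
    """
    out = []
    for i, t in enumerate(cur):
        if i < len(prev):
            p = prev[i]
            if p.type == t.type and p.value == t.value:
                out.append(IdToken(MATCH, 0, t.slot))
                continue
            if p.type == NUMERIC and t.type == NUMERIC and \
                    0 <= t.value - p.value <= 255:
                out.append(IdToken(DELTA, t.value - p.value, t.slot))
                continue
        out.append(IdToken(t.type, t.value, t.slot))
    return out


def resolve_tokens(prev, diffed) -> list:
    """Inverse of :func:`diff_tokens` given the previous literal tokens."""
    out = []
    for i, t in enumerate(diffed):
        if t.type == MATCH:
            p = prev[i]
            out.append(IdToken(p.type, p.value, i + 1))
        elif t.type == DELTA:
            out.append(IdToken(NUMERIC, prev[i].value + t.value, i + 1))
        else:
            out.append(IdToken(t.type, t.value, i + 1))
    return out


# ---------------------------------------------------------------------------
# fqzcomp-style stream coding
# ---------------------------------------------------------------------------

_CHR_BASE = 32            # coded characters span ASCII 32..126
_CHR_ALPHABET = 96        # 95 characters + terminator symbol 95
_CHR_TERM = 95


class _TokenisedModels:
    """Per-slot model bank for the tokenized identifier stream."""

    def __init__(self) -> None:
        self.type_m = [DirectContextModel(7) for _ in range(MAX_TOKENS + 1)]
        self.char_m = [DirectContextModel(_CHR_ALPHABET)
                       for _ in range(MAX_TOKENS + 1)]
        self.num_m = [[DirectContextModel(256) for _ in range(4)]
                      for _ in range(MAX_TOKENS + 1)]
        self.cont_m = [DirectContextModel(2) for _ in range(MAX_TOKENS + 1)]
        self.delta_m = [DirectContextModel(256) for _ in range(MAX_TOKENS + 1)]
        self.zero_m = [DirectContextModel(256) for _ in range(MAX_TOKENS + 1)]
        self.fallback_m = DirectContextModel(2)
        # string-delta models (also used for fallback records)
        self.prefix_m = DirectContextModel(256)
        self.suffix_m = DirectContextModel(_CHR_ALPHABET)


def _encode_number(enc, models, cont, slot, value) -> None:
    first = True
    while first or value:
        first = False
        chunk = value & 0xFFFFFFFF
        value >>= 32
        for j in range(4):
            models[slot][j].encode(enc, 0, (chunk >> (8 * j)) & 0xFF)
        cont[slot].encode(enc, 0, 1 if value else 0)


def _decode_number(dec, models, cont, slot) -> int:
    value = 0
    shift = 0
    while True:
        chunk = 0
        for j in range(4):
            chunk |= models[slot][j].decode(dec, 0) << (8 * j)
        value |= chunk << shift
        shift += 32
        if not cont[slot].decode(dec, 0):
            return value


def _encode_chars(enc, model, slot, s: str) -> None:
    for ch in s:
        model[slot].encode(enc, 0, ord(ch) - _CHR_BASE)
    model[slot].encode(enc, 0, _CHR_TERM)


def _decode_chars(dec, model, slot) -> str:
    out = []
    while True:
        sym = model[slot].decode(dec, 0)
        if sym == _CHR_TERM:
            return "".join(out)
        out.append(chr(sym + _CHR_BASE))


def _encode_zero_run(enc, model, slot, n: int) -> None:
    while n >= 255:
        model[slot].encode(enc, 0, 255)
        n -= 255
    model[slot].encode(enc, 0, n)


def _decode_zero_run(dec, model, slot) -> int:
    n = 0
    while True:
        b = model[slot].decode(dec, 0)
        n += b
        if b < 255:
            return n


def _encode_string_delta(enc, mod, prev: str, cur: str) -> None:
    n = 0
    limit = min(len(prev), len(cur), 255)
    while n < limit and prev[n] == cur[n]:
        n += 1
    mod.prefix_m.encode(enc, 0, n)
    for ch in cur[n:]:
        mod.suffix_m.encode(enc, 0, ord(ch) - _CHR_BASE)
    mod.suffix_m.encode(enc, 0, _CHR_TERM)


def _decode_string_delta(dec, mod, prev: str) -> str:
    n = mod.prefix_m.decode(dec, 0)
    out = [prev[:n]]
    while True:
        sym = mod.suffix_m.decode(dec, 0)
        if sym == _CHR_TERM:
            return "".join(out)
        out.append(chr(sym + _CHR_BASE))


class IdEncoder:
    """Streaming identifier encoder (record-at-a-time)."""

    def __init__(self, mode: str = "tokenized", alnum: bool = False) -> None:
        if mode not in ("tokenized", "string_delta"):
            raise ValueError(f"unknown identifier mode {mode!r}")
        self.mode = mode
        self.alnum = alnum
        self.enc = RangeEncoder()
        self.mod = _TokenisedModels()
        self._prev_tokens: list = []
        self._prev_id = ""

    def add(self, identifier: str) -> None:
        if "\n" in identifier or "\r" in identifier:
            raise ValueError("identifier contains a newline")
        enc, mod = self.enc, self.mod
        if self.mode == "string_delta":
            _encode_string_delta(enc, mod, self._prev_id, identifier)
            self._prev_id = identifier
            return
        tokens = tokenize_id(identifier, self.alnum)
        ok = len(tokens) <= MAX_TOKENS and all(
            ord(c) >= _CHR_BASE and ord(c) <= 126 for t in tokens
            if t.type in (ALPHA, PUNCT) for c in t.value)
        if not ok:
            mod.fallback_m.encode(enc, 0, 1)
            _encode_string_delta(enc, mod, self._prev_id, identifier)
            self._prev_id = identifier
            self._prev_tokens = []
            return
        mod.fallback_m.encode(enc, 0, 0)
        diffed = diff_tokens(self._prev_tokens, tokens)
        for t in diffed:
            slot = t.slot
            mod.type_m[slot].encode(enc, 0, t.type)
            if t.type == ALPHA or t.type == PUNCT:
                _encode_chars(enc, mod.char_m, slot, t.value)
            elif t.type == NUMERIC:
                _encode_number(enc, mod.num_m, mod.cont_m, slot, t.value)
            elif t.type == LEADING_ZERO_NUMERIC:
                _encode_zero_run(enc, mod.zero_m, slot, t.value)
            elif t.type == DELTA:
                mod.delta_m[slot].encode(enc, 0, t.value)
        end_slot = min(len(diffed) + 1, MAX_TOKENS)
        mod.type_m[end_slot].encode(enc, 0, _END)
        self._prev_tokens = tokens
        self._prev_id = identifier

    def finish(self) -> bytes:
        return self.enc.flush()


class IdDecoder:
    """Streaming inverse of :class:`IdEncoder`."""

    def __init__(self, data: bytes, mode: str = "tokenized",
                 alnum: bool = False) -> None:
        self.mode = mode
        self.dec = RangeDecoder(data)
        self.mod = _TokenisedModels()
        self._prev_tokens: list = []
        self._prev_id = ""

    def get(self) -> str:
        dec, mod = self.dec, self.mod
        if self.mode == "string_delta":
            ident = _decode_string_delta(dec, mod, self._prev_id)
            self._prev_id = ident
            return ident
        if mod.fallback_m.decode(dec, 0):
            ident = _decode_string_delta(dec, mod, self._prev_id)
            self._prev_id = ident
            self._prev_tokens = []
            return ident
        diffed = []
        slot = 1
        while True:
            ttype = mod.type_m[slot].decode(dec, 0)
            if ttype == _END:
                break
            if ttype == ALPHA or ttype == PUNCT:
                val = _decode_chars(dec, mod.char_m, slot)
            elif ttype == NUMERIC:
                val = _decode_number(dec, mod.num_m, mod.cont_m, slot)
            elif ttype == LEADING_ZERO_NUMERIC:
                val = _decode_zero_run(dec, mod.zero_m, slot)
            elif ttype == DELTA:
                val = mod.delta_m[slot].decode(dec, 0)
            else:
                val = 0
            diffed.append(IdToken(ttype, val, slot))
            if slot < MAX_TOKENS:
                slot += 1
        tokens = resolve_tokens(self._prev_tokens, diffed)
        ident = detokenize(tokens)
        self._prev_tokens = tokens
        self._prev_id = ident
        return ident


def encode_id_stream(ids, mode: str = "tokenized", alnum: bool = False) -> bytes:
    """Losslessly compress a sequence of identifier lines."""
    enc = IdEncoder(mode, alnum)
    for i in ids:
        enc.add(i)
    return enc.finish()


def decode_id_stream(data: bytes, n: int, mode: str = "tokenized",
                     alnum: bool = False) -> list:
    """Inverse of :func:`encode_id_stream`."""
    if n == 0:
        return []
    dec = IdDecoder(data, mode, alnum)
    return [dec.get() for _ in range(n)]


# ---------------------------------------------------------------------------
# fastqz line-delta preprocessing
# ---------------------------------------------------------------------------

@dataclass
class LineDelta:
    """fastqz identifier record: (column)(increment)(match_len)"literal"(0).

    ``column`` is the 1-based position of the last digit of the decimal
    string that receives ``increment`` (0 means "no increment").  After
    adjusting the previous line, its first ``match_len`` bytes are copied
    and ``literal`` appended.  The terminator 0 replaces the newline.
    """
    column: int
    increment: int
    match_len: int
    literal: str
    terminator: int = 0


_DIGITS_RE = re.compile(r"[0-9]+")


def _adjust(prev: str, start: int, end: int, inc: int) -> str:
    """Add ``inc`` to prev[start:end] (a digit run), preserving width."""
    run = prev[start:end]
    s2 = str(int(run) + inc)
    if len(s2) < len(run):
        s2 = s2.zfill(len(run))
    return prev[:start] + s2 + prev[end:]


def _common_prefix(a: str, b: str) -> int:
    n = 0
    limit = min(len(a), len(b))
    while n < limit and a[n] == b[n]:
        n += 1
    return n


def fastqz_delta(prev: str, cur: str) -> LineDelta:
    """Delta-encode ``cur`` against ``prev`` fastqz-style.

    Chooses the (column, increment<=255) pair maximising the copied prefix
    after adjustment; an increment that would need to exceed 255 (or that
    never beats the plain prefix) degrades to mismatch coding with
    column=0, increment=0.

    Only the digit run of ``prev`` covering the first divergent byte can
    lengthen the copy (an increment always rewrites that run's last digit,
    so changing any earlier run would break the already-matching prefix,
    and a later run lies beyond the first mismatch).  The increment equal
    to the difference of the decimal fields is tried first; if the copy it
    yields runs past the adjusted digits it is provably maximal, otherwise
    all 255 admissible increments are searched.
    """
    if "\n" in prev or "\n" in cur:
        raise ValueError("lines must not contain newlines")
    d = _common_prefix(prev, cur)
    best = (0, 0, min(d, 255))
    run = None
    if d < len(prev):
        # maximal digit run of prev containing position d
        start = d
        if start < len(prev) and prev[start].isdigit():
            while start > 0 and prev[start - 1].isdigit():
                start -= 1
            end = d
            while end < len(prev) and prev[end].isdigit():
                end += 1
            if end <= 255:
                run = (start, end)
    if run is not None:
        start, end = run
        v = int(prev[start:end])
        tried = set()
        # fast path: increment implied by cur's decimal field at `start`
        mo2 = _DIGITS_RE.match(cur, start)
        if mo2:
            inc = int(mo2.group(0)) - v
            if 1 <= inc <= 255:
                adjusted = _adjust(prev, start, end, inc)
                mlen = min(_common_prefix(adjusted, cur), 255)
                tried.add(inc)
                if mlen > best[2]:
                    best = (end, inc, mlen)
                # copy running past the rewritten digits cannot be beaten
                new_end = start + len(str(v + inc).zfill(end - start))
                if mlen >= min(new_end + 1, 255) or mlen == 255:
                    tried = None
        if tried is not None:
            for inc in range(1, 256):
                if inc in tried:
                    continue
                adjusted = _adjust(prev, start, end, inc)
                mlen = min(_common_prefix(adjusted, cur), 255)
                if mlen > best[2]:
                    best = (end, inc, mlen)
    column, inc, mlen = best
    return LineDelta(column, inc, mlen, cur[mlen:])


def apply_line_delta(prev: str, d: LineDelta) -> str:
    """Reconstruct the current line from the previous one and a delta."""
    line = prev
    if d.column:
        end = d.column
        start = end
        while start > 0 and line[start - 1].isdigit():
            start -= 1
        line = _adjust(line, start, end, d.increment)
    return line[:d.match_len] + d.literal


def serialize_delta(d: LineDelta) -> bytes:
    lit = d.literal.encode("ascii")
    if 0 in lit:
        raise ValueError("literal may not contain NUL")
    return bytes([d.column, d.increment, d.match_len]) + lit + b"\x00"


# ---------------------------------------------------------------------------
# fastqz slow-mode coding of the delta byte stream
# ---------------------------------------------------------------------------

def _hash2(a: int, b: int) -> int:
    return (a * 0x9E3779B1 + b) & 0xFFFFFFF


class _FastqzIdCM:
    """Context-mixed bit coder for serialized LineDelta records.

    Four models as in the fastqz identifier coder: two direct models over
    the last 1 and 2 bytes of the current line, two indirect (bit-history)
    models over the last 3 and 4 bytes; every context also hashes in the
    column number, the byte at the same column of the previous line, and
    the already-coded bits of the current byte.  Mixing weights are
    selected by the column number.
    """

    def __init__(self) -> None:
        self.m1 = BitContextModel()
        self.m2 = BitContextModel()
        self.m3 = BitHistoryModel()
        self.m4 = BitHistoryModel()
        self.mixer = Mixer(4)
        self.prev_line = b""
        self.cur_line = bytearray()

    def _keys(self, bitctx: int):
        line = self.cur_line
        col = len(line)
        pb = self.prev_line[col] if col < len(self.prev_line) else 0
        base = _hash2(col & 63, pb)
        h1 = line[-1] if line else 0
        h2 = h1 | (line[-2] << 8 if len(line) > 1 else 0)
        h3 = h2 | (line[-3] << 16 if len(line) > 2 else 0)
        h4 = h3 | (line[-4] << 24 if len(line) > 3 else 0)
        return (
            _hash2(base, _hash2(h1, bitctx)),
            _hash2(base, _hash2(h2 ^ 0x55, bitctx)),
            _hash2(base, _hash2(h3 ^ 0xAA, bitctx)),
            _hash2(base, _hash2(h4 ^ 0xFF, bitctx)),
        )

    def _code_byte(self, rc, byte=None):
        bitctx = 1
        for k in range(8):
            k1, k2, k3, k4 = self._keys(bitctx)
            probs = (self.m1.predict(k1), self.m2.predict(k2),
                     self.m3.predict(k3), self.m4.predict(k4))
            p = self.mixer.mix(probs, len(self.cur_line) & 63)
            if byte is None:
                bit = rc.decode_bit(p)
            else:
                bit = (byte >> (7 - k)) & 1
                rc.encode_bit(bit, p)
            self.mixer.update(bit)
            self.m1.update(k1, bit)
            self.m2.update(k2, bit)
            self.m3.update(k3, bit)
            self.m4.update(k4, bit)
            bitctx = (bitctx << 1) | bit
        value = bitctx & 0xFF
        self.cur_line.append(value)
        # a record is 3 header bytes, a NUL-free literal, then a NUL
        if value == 0 and len(self.cur_line) >= 4:
            self.prev_line = bytes(self.cur_line)
            self.cur_line = bytearray()
        return value

    def encode_record(self, rc: RangeEncoder, data: bytes) -> None:
        for b in data:
            self._code_byte(rc, b)

    def decode_record(self, rc: RangeDecoder) -> bytes:
        out = bytearray()
        while True:
            b = self._code_byte(rc)
            out.append(b)
            if b == 0 and len(out) >= 4:
                return bytes(out)


class FastqzIdEncoder:
    """Streaming fastqz identifier encoder (fast=raw codes, slow=CM)."""

    def __init__(self, slow: bool = False) -> None:
        self.slow = slow
        self._prev = ""
        self._raw = bytearray()
        self._rc = RangeEncoder() if slow else None
        self._cm = _FastqzIdCM() if slow else None

    def add(self, identifier: str) -> None:
        d = fastqz_delta(self._prev, identifier)
        rec = serialize_delta(d)
        if self.slow:
            self._cm.encode_record(self._rc, rec)
        else:
            self._raw += rec
        self._prev = identifier

    def finish(self) -> bytes:
        return self._rc.flush() if self.slow else bytes(self._raw)


class FastqzIdDecoder:
    """Streaming inverse of :class:`FastqzIdEncoder`."""

    def __init__(self, data: bytes, slow: bool = False) -> None:
        self.slow = slow
        self._prev = ""
        if slow:
            self._rc = RangeDecoder(data)
            self._cm = _FastqzIdCM()
        else:
            self._data = data
            self._pos = 0

    def _next_record(self) -> bytes:
        if self.slow:
            return self._cm.decode_record(self._rc)
        end = self._data.index(b"\x00", self._pos + 3)
        rec = self._data[self._pos:end + 1]
        self._pos = end + 1
        return rec

    def get(self) -> str:
        rec = self._next_record()
        d = LineDelta(rec[0], rec[1], rec[2], rec[3:-1].decode("ascii"))
        ident = apply_line_delta(self._prev, d)
        self._prev = ident
        return ident
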