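"""Adaptive arithmetic (range) coding engine and the predictor zoo.

This module provides the shared machinery used by every codec in the
package:

* a byte-wise 32-bit range coder (:class:`RangeEncoder` /
  :class:`RangeDecoder`) with carry handling, supporting both a
  multi-symbol frequency interface and a fast binary interface driven by
  12-bit probabilities;
* :class:`DirectContextModel` — adaptive symbol-frequency tables addressed
  by a context key (8-bit counters, halved on overflow);
* :class:`AdaptiveBit` / :class:`BitContextModel` — direct binary
  predictors updated by exponential decay toward the observed bit;
* :class:`BitHistoryModel` — an indirect model mapping a context hash to an
  8-bit bit-history state, which in turn maps to an adaptive probability;
* :class:`Mixer` — logistic (stretch/squash-domain) weighted averaging of
  several binary predictions, with gradient weight updates;
* :class:`SSE` — a secondary symbol estimator refining a prediction by
  mixing it with a constant in the logistic domain, weights selected by a
  per-context bit history;
* :class:`MatchModel` — predicts continuation of the last occurrence of
  the current context with confidence 1 - 1/(match length in bits).

All probabilities on the coding path are 12-bit integers in [1, 4095]
(a floor of 1/4096 keeps code lengths finite) and the stretch/squash maps
are integer lookup tables, so encoder and decoder are bit-identical across
platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PROB_BITS", "PROB_ONE", "PROB_FLOOR", "PROB_CEIL",
    "stretch", "squash",
    "RangeEncoder", "RangeDecoder",
    "Prediction", "DirectContextModel", "AdaptiveBit", "BitContextModel",
    "BitHistoryModel", "Mixer", "SSE", "MatchModel",
    "rc_encode", "rc_decode", "mix", "match_predict",
]

PROB_BITS = 12
PROB_ONE = 1 << PROB_BITS          # 4096
PROB_FLOOR = 1                     # 1/4096
PROB_CEIL = PROB_ONE - 1           # 4095/4096

_TOP = 1 << 24
_MASK32 = 0xFFFFFFFF

# ---------------------------------------------------------------------------
# stretch / squash lookup tables (integer, 4096 entries each direction)
# ---------------------------------------------------------------------------
# squash(x) = 4096 / (1 + e^(-x/256)), x clamped to [-2047, 2047]
_SQUASH = [0] * 4095
for _x in range(-2047, 2048):
    _v = int(round(PROB_ONE / (1.0 + math.exp(-_x / 256.0))))
    _SQUASH[_x + 2047] = min(PROB_CEIL, max(PROB_FLOOR, _v))

# stretch(p) = 256 * ln(p / (4096-p)) for p on the clamped 12-bit grid
_STRETCH = [0] * PROB_ONE
for _p in range(PROB_ONE):
    _pc = min(PROB_CEIL, max(PROB_FLOOR, _p))
    _v = int(round(256.0 * math.log(_pc / (PROB_ONE - _pc))))
    _STRETCH[_p] = min(2047, max(-2047, _v))


def squash(x: int) -> int:
    """Inverse logistic: stretch-domain value -> 12-bit probability."""
    if x < -2047:
        x = -2047
    elif x > 2047:
        x = 2047
    return _SQUASH[x + 2047]


def stretch(p: int) -> int:
    """Logistic transform of a 12-bit probability (scale 256 per logit)."""
    return _STRETCH[p & (PROB_ONE - 1)] if 0 <= p < PROB_ONE else _STRETCH[PROB_CEIL if p >= PROB_ONE else PROB_FLOOR]


# ---------------------------------------------------------------------------
# Range coder
# ---------------------------------------------------------------------------

class RangeEncoder:
    """32-bit low/range byte-wise range encoder with carry counting.

    The first output byte is a dummy produced by the cache mechanism; the
    decoder skips it.  ``flush()`` appends 5 tail bytes so the decoder can
    always refill; total framing overhead is a small constant.
    """

    def __init__(self) -> None:
        self.low = 0
        self.range = _MASK32
        self._cache = 0
        self._cache_size = 1
        self.out = bytearray()

    def _shift_low(self) -> None:
        low = self.low
        if low < 0xFF000000 or low > _MASK32:
            carry = low >> 32
            cache = self._cache
            out = self.out
            out.append((cache + carry) & 0xFF)
            for _ in range(self._cache_size - 1):
                out.append((0xFF + carry) & 0xFF)
            self._cache_size = 0
            self._cache = (low >> 24) & 0xFF
        self._cache_size += 1
        self.low = (low << 8) & _MASK32

    def encode_freq(self, cum: int, freq: int, tot: int) -> None:
        """Encode a symbol occupying [cum, cum+freq) of a total of `tot`."""
        r = self.range // tot
        self.low += r * cum
        self.range = r * freq
        while self.range < _TOP:
            self._shift_low()
            self.range = (self.range << 8) & _MASK32

    def encode_bit(self, bit: int, p1: int) -> None:
        """Encode one bit given a 12-bit probability that the bit is 1."""
        bound = (self.range >> PROB_BITS) * p1
        if bit:
            self.range = bound
        else:
            self.low += bound
            self.range -= bound
        while self.range < _TOP:
            self._shift_low()
            self.range = (self.range << 8) & _MASK32

    def flush(self) -> bytes:
        for _ in range(5):
            self._shift_low()
        return bytes(self.out)


class RangeDecoder:
    """Mirror of :class:`RangeEncoder`; raises on truncated input."""

    def __init__(self, data: bytes) -> None:
        self._data = data
        self._pos = 1          # skip the encoder's dummy first byte
        self.range = _MASK32
        self.code = 0
        for _ in range(4):
            self.code = (self.code << 8) | self._next_byte()
        self._r = 1

    def _next_byte(self) -> int:
        pos = self._pos
        if pos >= len(self._data):
            raise ValueError("truncated range-coded stream")
        self._pos = pos + 1
        return self._data[pos]

    def decode_target(self, tot: int) -> int:
        self._r = self.range // tot
        t = self.code // self._r
        return tot - 1 if t >= tot else t

    def decode_update(self, cum: int, freq: int) -> None:
        self.code -= self._r * cum
        self.range = self._r * freq
        while self.range < _TOP:
            self.code = ((self.code << 8) | self._next_byte()) & _MASK32
            self.range = (self.range << 8) & _MASK32

    def decode_bit(self, p1: int) -> int:
        bound = (self.range >> PROB_BITS) * p1
        if self.code < bound:
            bit = 1
            self.range = bound
        else:
            bit = 0
            self.code -= bound
            self.range -= bound
        while self.range < _TOP:
            self.code = ((self.code << 8) | self._next_byte()) & _MASK32
            self.range = (self.range << 8) & _MASK32
        return bit


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    """Probability that the next bit is 1, clamped inside (0, 1)."""

    p: float

    def __post_init__(self) -> None:
        floor = PROB_FLOOR / PROB_ONE
        ceil = PROB_CEIL / PROB_ONE
        self.p = min(ceil, max(floor, self.p))


class DirectContextModel:
    """Adaptive per-context symbol frequency table with 8-bit counters.

    Coding frequencies are ``count + 1`` so every symbol stays codable.
    On overflow (any counter exceeding ``rescale_limit``) all counters in
    that context are halved rounding up, which preserves the ordering of
    the counts and never drives a nonzero count to zero.

    The default increment of +4 against the 255 cap keeps the
    steady-state probability quantisation (roughly inc / total) inside
    the coder's 1% optimality budget while still tracking nonstationary
    statistics; codecs that want faster adaptation pass a larger ``inc``.
    """

    def __init__(self, alphabet_size: int, inc: int = 4,
                 rescale_limit: int = 255) -> None:
        if alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        self.alphabet_size = alphabet_size
        self.inc = inc
        self.rescale_limit = rescale_limit
        self.table: dict = {}

    def counts(self, key) -> list:
        c = self.table.get(key)
        if c is None:
            c = [0] * self.alphabet_size
            self.table[key] = c
        return c

    def predict(self, key) -> list:
        """Per-symbol probabilities (floats summing to 1) for tests/tools."""
        c = self.table.get(key)
        if c is None:
            n = self.alphabet_size
            return [1.0 / n] * n
        tot = sum(c) + self.alphabet_size
        return [(x + 1) / tot for x in c]

    def update(self, key, sym: int) -> None:
        c = self.counts(key)
        c[sym] += self.inc
        if c[sym] > self.rescale_limit:
            for i, x in enumerate(c):
                c[i] = (x + 1) >> 1

    def encode(self, enc: RangeEncoder, key, sym: int) -> None:
        if not 0 <= sym < self.alphabet_size:
            raise ValueError(f"symbol {sym} out of range for alphabet "
                             f"of {self.alphabet_size}")
        c = self.counts(key)
        cum = 0
        for i in range(sym):
            cum += c[i]
        cum += sym                       # +1 smoothing, accumulated
        enc.encode_freq(cum, c[sym] + 1, sum(c) + self.alphabet_size)
        self.update(key, sym)

    def decode(self, dec: RangeDecoder, key) -> int:
        c = self.counts(key)
        tot = sum(c) + self.alphabet_size
        target = dec.decode_target(tot)
        cum = 0
        sym = 0
        for i, x in enumerate(c):
            nxt = cum + x + 1
            if target < nxt:
                sym = i
                break
            cum = nxt
        dec.decode_update(cum, c[sym] + 1, )
        self.update(key, sym)
        return sym


class AdaptiveBit:
    """A single adaptive binary probability (12-bit, shift update)."""

    __slots__ = ("p", "rate")

    def __init__(self, p: int = PROB_ONE // 2, rate: int = 5) -> None:
        self.p = p
        self.rate = rate

    def update(self, bit: int) -> None:
        if bit:
            self.p += (PROB_ONE - self.p) >> self.rate
            if self.p > PROB_CEIL:
                self.p = PROB_CEIL
        else:
            self.p -= self.p >> self.rate
            if self.p < PROB_FLOOR:
                self.p = PROB_FLOOR


class BitContextModel:
    """Direct binary context model: context key -> adaptive probability."""

    def __init__(self, rate: int = 5) -> None:
        self.rate = rate
        self.table: dict = {}

    def predict(self, key) -> int:
        return self.table.get(key, PROB_ONE // 2)

    def update(self, key, bit: int) -> None:
        p = self.table.get(key, PROB_ONE // 2)
        if bit:
            p += (PROB_ONE - p) >> self.rate
            if p > PROB_CEIL:
                p = PROB_CEIL
        else:
            p -= p >> self.rate
            if p < PROB_FLOOR:
                p = PROB_FLOOR
        self.table[key] = p


# 8-bit bit-history state machine: state 0 is "no history"; other states
# encode (last bit, saturating run length 1..40).  81 states total.
_HIST_CAP = 40


def history_next(state: int, bit: int) -> int:
    """Deterministic transition of the 8-bit bit-history state."""
    if state == 0:
        return 1 + bit * _HIST_CAP
    b = (state - 1) // _HIST_CAP
    n = (state - 1) % _HIST_CAP + 1
    if bit == b:
        n = min(n + 1, _HIST_CAP)
        return 1 + b * _HIST_CAP + (n - 1)
    return 1 + bit * _HIST_CAP


class BitHistoryModel:
    """Indirect context model: context hash -> 8-bit history state -> p.

    The state map is shared across contexts of the model, as in PAQ-style
    indirect models: rare contexts borrow statistics from common history
    patterns.
    """

    N_STATES = 2 * _HIST_CAP + 1

    def __init__(self, rate: int = 4) -> None:
        self.table: dict = {}
        self.rate = rate
        self.state_map = [PROB_ONE // 2] * self.N_STATES
        # seed the map with the run-length's natural bias
        for b in (0, 1):
            for n in range(1, _HIST_CAP + 1):
                s = 1 + b * _HIST_CAP + (n - 1)
                p1 = (n + 1) / (n + 2)
                p = int(round(p1 * PROB_ONE)) if b else int(round((1 - p1) * PROB_ONE))
                self.state_map[s] = min(PROB_CEIL, max(PROB_FLOOR, p))

    def predict(self, key) -> int:
        return self.state_map[self.table.get(key, 0)]

    def update(self, key, bit: int) -> None:
        st = self.table.get(key, 0)
        p = self.state_map[st]
        if bit:
            p += (PROB_ONE - p) >> self.rate
        else:
            p -= p >> self.rate
        self.state_map[st] = min(PROB_CEIL, max(PROB_FLOOR, p))
        self.table[key] = history_next(st, bit)


class Mixer:
    """Logistic mixer: weighted averaging of predictions in stretch domain.

    Weights are stored per selector value in 16.16 fixed point and start at
    1/n each, so with agreeing inputs the output equals the common input.
    The update is a gradient step on coding loss with a fixed learning rate
    (0.002 in the stretch domain, realised as an integer shift).
    """

    def __init__(self, n_inputs: int, lr_shift: int = 13) -> None:
        if n_inputs < 1:
            raise ValueError("mixer needs at least one input")
        self.n_inputs = n_inputs
        self.lr_shift = lr_shift
        self.weights: dict = {}
        self._st: list = [0] * n_inputs
        self._sel = None
        self._p = PROB_ONE // 2

    def _w(self, sel) -> list:
        w = self.weights.get(sel)
        if w is None:
            w = [(1 << 16) // self.n_inputs] * self.n_inputs
            self.weights[sel] = w
        return w

    def mix(self, probs: list, sel=0) -> int:
        """Mix 12-bit probabilities; remembers state for ``update``."""
        w = self._w(sel)
        st = self._st
        dot = 0
        for i, p in enumerate(probs):
            s = _STRETCH[p]
            st[i] = s
            dot += w[i] * s
        self._sel = sel
        self._p = squash(dot >> 16)
        return self._p

    def update(self, bit: int) -> None:
        err = (bit << PROB_BITS) - self._p
        w = self.weights[self._sel]
        st = self._st
        sh = self.lr_shift
        for i in range(self.n_inputs):
            w[i] += (st[i] * err) >> sh


class SSE:
    """Secondary symbol estimation via logistic mixing with a constant.

    Each context key owns an 8-bit bit history; the history state selects a
    pair of weights (w_p, w_c) and the refined prediction is
    ``squash((w_p*stretch(p) + w_c*C) >> 16)`` with C a fixed stretch-domain
    constant.  Weights adapt like mixer weights.
    """

    CONST = 256  # one logit

    def __init__(self, lr_shift: int = 13) -> None:
        self.histories: dict = {}
        self.weights: dict = {}      # (history state) -> [w_p, w_c]
        self.lr_shift = lr_shift
        self._key = None
        self._st = 0
        self._state = 0
        self._p = PROB_ONE // 2

    def refine(self, p: int, key) -> int:
        st = self.histories.get(key, 0)
        w = self.weights.get(st)
        if w is None:
            w = [1 << 16, 0]
            self.weights[st] = w
        s = _STRETCH[p]
        self._key, self._st, self._state = key, s, st
        self._p = squash((w[0] * s + w[1] * self.CONST) >> 16)
        return self._p

    def update(self, bit: int) -> None:
        err = (bit << PROB_BITS) - self._p
        w = self.weights[self._state]
        sh = self.lr_shift
        w[0] += (self._st * err) >> sh
        w[1] += (self.CONST * err) >> sh
        self.histories[self._key] = history_next(
            self.histories.get(self._key, 0), bit)


class MatchModel:
    """Match model over a byte stream, predicting bit continuations.

    Keeps a history buffer of coded bytes and a hash index of the last
    position of each ``order``-byte context.  While a match is active the
    next bit is predicted with probability 1 - 1/(match length in bits);
    a mispredicted bit cancels the match.
    """

    def __init__(self, order: int = 5, min_len: int = 1) -> None:
        self.order = order
        self.min_len = min_len
        self.buffer = bytearray()
        self.hash_index: dict = {}
        self.match_pos = -1
        self.match_len = 0            # in bytes
        self._bitpos = 0
        self._expected = -1

    # -- byte-boundary maintenance -------------------------------------
    def _context_key(self) -> int:
        o = self.order
        if len(self.buffer) < o:
            return -1
        h = 0
        for b in self.buffer[-o:]:
            h = (h * 0x2545F491 + b + 1) & 0xFFFFFFFF
        return h

    def push_byte(self, byte: int) -> None:
        """Append a fully coded byte and refresh the match state."""
        buf = self.buffer
        if self.match_pos >= 0 and self.match_pos < len(buf) and \
                buf[self.match_pos] == byte:
            self.match_pos += 1
            self.match_len += 1
        else:
            self.match_pos = -1
            self.match_len = 0
        buf.append(byte)
        key = self._context_key()
        if key != -1:
            if self.match_pos < 0:
                cand = self.hash_index.get(key, -1)
                if cand >= 0:
                    self.match_pos = cand
                    self.match_len = self.min_len
            self.hash_index[key] = len(buf)
        self._bitpos = 0

    # -- bit-level prediction ------------------------------------------
    def predict_bit(self, part: int, nbits: int) -> int:
        """12-bit probability for the next bit of the current byte.

        ``part`` holds the bits already coded this byte (MSB first),
        ``nbits`` how many.  Returns 2048 when no usable match is active.
        """
        if self.match_pos < 0 or self.match_pos >= len(self.buffer):
            self._expected = -1
            return PROB_ONE // 2
        b = self.buffer[self.match_pos]
        if nbits and (b >> (8 - nbits)) != part:
            # current byte already deviates from the match
            self._expected = -1
            return PROB_ONE // 2
        bit = (b >> (7 - nbits)) & 1
        self._expected = bit
        len_bits = self.match_len * 8 + nbits
        if len_bits < 2:
            return PROB_ONE // 2
        delta = PROB_ONE // len_bits
        if delta < 1:
            delta = 1
        p = PROB_ONE - delta if bit else delta
        return min(PROB_CEIL, max(PROB_FLOOR, p))

    def update_bit(self, bit: int) -> None:
        if self._expected != -1 and bit != self._expected:
            self.match_pos = -1
            self.match_len = 0


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def rc_encode(symbols, model: DirectContextModel, context_fn=None) -> bytes:
    """Arithmetic-code a symbol sequence under a direct context model.

    ``context_fn`` maps the list of previously coded symbols to a context
    key (defaults to order-0).  The model is mutated; pass a fresh model
    with the same parameters to :func:`rc_decode`.
    """
    enc = RangeEncoder()
    history: list = []
    for s in symbols:
        key = context_fn(history) if context_fn else 0
        model.encode(enc, key, s)
        history.append(s)
    return enc.flush()


def rc_decode(data: bytes, n: int, model: DirectContextModel,
              context_fn=None) -> list:
    """Inverse of :func:`rc_encode` given identical model config."""
    if n == 0:
        return []
    dec = RangeDecoder(data)
    history: list = []
    for _ in range(n):
        key = context_fn(history) if context_fn else 0
        history.append(model.decode(dec, key))
    return history


def mix(predictions, selector, mixer: Mixer) -> Prediction:
    """Combine float predictions by weighted logistic averaging."""
    if not predictions:
        raise ValueError("mix requires at least one prediction")
    probs = [min(PROB_CEIL, max(PROB_FLOOR, int(round(p.p * PROB_ONE))))
             for p in predictions]
    return Prediction(mixer.mix(probs, selector) / PROB_ONE)


def match_predict(m: MatchModel) -> Prediction:
    """Prediction that the next bit continues the active match.

    With a match of ``len >= 2`` bits the continuation probability is
    1 - 1/len; without a match the model is uninformed (0.5).
    """
    len_bits = m.match_len * 8 + m._bitpos
    if m.match_pos < 0 or len_bits < 2:
        return Prediction(0.5)
    return Prediction(1.0 - 1.0 / len_bits)
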