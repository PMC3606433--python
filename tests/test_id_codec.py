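"""Identifier tokenization, delta coding and stream round trips."""

import random
import string

import pytest
from hypothesis import given, settings, strategies as st

from fqzlite.id_codec import (
    ALPHA, DELTA, LEADING_ZERO_NUMERIC, MATCH, NUMERIC, PUNCT,
    FastqzIdDecoder, FastqzIdEncoder, LineDelta, apply_line_delta,
    decode_id_stream, detokenize, diff_tokens, encode_id_stream,
    fastqz_delta, tokenize_id,
)

ID1 = "@SRR062634.2724180 HWI-EAS110_103327062:6:13:11133:11572/1"
ID2 = "@SRR062634.2724181 HWI-EAS110_103327062:6:13:11133:5630/1"

_ID_CHARS = string.ascii_letters + string.digits + " .:/_-@#()=+~"


class TestTokenize:
    def test_worked_srr_identifier_split(self):
        toks = tokenize_id("@SRR062634.3364 HWI-EAS110_103327062:6:1:1944:962/2")
        kinds = [(t.type, t.value) for t in toks[:6]]
        assert kinds == [
            (PUNCT, "@"), (ALPHA, "SRR"), (LEADING_ZERO_NUMERIC, 1),
            (NUMERIC, 62634), (PUNCT, "."), (NUMERIC, 3364)]
        assert toks[0].slot == 1 and toks[5].slot == 6

    def test_empty_identifier(self):
        assert tokenize_id("") == []

    def test_leading_zero_runs_split_from_digits(self):
        toks = tokenize_id("abc007xyz")
        assert [(t.type, t.value) for t in toks] == [
            (ALPHA, "abc"), (LEADING_ZERO_NUMERIC, 2), (NUMERIC, 7),
            (ALPHA, "xyz")]

    @given(st.text(alphabet=_ID_CHARS, max_size=50))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_roundtrip_property(self, s):
        assert detokenize(tokenize_id(s)) == s

    def test_alnum_mode_merges_letter_digit_runs(self):
        toks = tokenize_id("EAS11X0_9", alnum=True)
        assert toks[0].type == ALPHA and toks[0].value == "EAS11X0"
        assert detokenize(toks) == "EAS11X0_9"


class TestDiffTokens:
    def test_identical_lines_are_all_match(self):
        a = tokenize_id(ID1)
        assert all(t.type == MATCH for t in diff_tokens(a, a))

    def test_incremented_numeric_field_becomes_delta(self):
        a = tokenize_id("x:962/2")
        b = tokenize_id("x:963/2")
        d = diff_tokens(a, b)
        types = [t.type for t in d]
        assert types.count(DELTA) == 1
        assert d[types.index(DELTA)].value == 1
        assert all(t == MATCH for i, t in enumerate(types) if t != DELTA) or \
            all(t.type in (MATCH, DELTA) for t in d)

    def test_decreasing_numeric_is_kept_literal(self):
        a = tokenize_id("n100")
        b = tokenize_id("n90")
        d = diff_tokens(a, b)
        assert d[1].type == NUMERIC and d[1].value == 90

    def test_delta_limited_to_255(self):
        a = tokenize_id("n1")
        b = tokenize_id("n300")
        assert diff_tokens(a, b)[1].type == NUMERIC


class TestStreams:
    def test_incrementing_identifiers_compress_below_4_bytes_each(self):
        rng = random.Random(5)
        ids = [f"@SRR062634.{i} HWI-EAS110_103327062:6:13:{1000 + i}:"
               f"{rng.randrange(10000)}/1" for i in range(1000)]
        data = encode_id_stream(ids, "tokenized")
        assert decode_id_stream(data, len(ids), "tokenized") == ids
        assert len(data) / len(ids) < 4

    def test_single_identifier_roundtrip(self):
        data = encode_id_stream(["@only one"], "tokenized")
        assert decode_id_stream(data, 1, "tokenized") == ["@only one"]

    def test_454_style_names_favour_string_delta(self):
        from fqzlite.simdata import SimProfile, _make_names
        import numpy as np
        prof = SimProfile(name_style="ls454")
        names = _make_names(400, prof, np.random.default_rng(3))
        t = encode_id_stream(names, "tokenized")
        s = encode_id_stream(names, "string_delta")
        assert decode_id_stream(s, len(names), "string_delta") == names
        assert len(s) < len(t)

    @pytest.mark.parametrize("mode", ["tokenized", "string_delta"])
    def test_arbitrary_ascii_roundtrip(self, mode, rng):
        ids = ["".join(rng.choice(_ID_CHARS)
                       for _ in range(rng.randrange(0, 60)))
               for _ in range(300)]
        data = encode_id_stream(ids, mode)
        assert decode_id_stream(data, len(ids), mode) == ids

    def test_slot_stability_between_streams(self):
        # streams identical except in one numeric field differ only in
        # that slot's coded statistics, hence sizes stay very close
        base = [f"@run.{i} lane:4:tile:{i}" for i in range(300)]
        alt = [f"@run.{i} lane:7:tile:{i}" for i in range(300)]
        assert abs(len(encode_id_stream(base)) - len(encode_id_stream(alt))) < 32


class TestFastqzDelta:
    def test_worked_example_column18_inc1_copy51(self):
        d = fastqz_delta(ID1, ID2)
        assert (d.column, d.increment, d.match_len, d.literal,
                d.terminator) == (18, 1, 51, "5630/1", 0)
        assert apply_line_delta(ID1, d) == ID2

    def test_identical_lines_full_copy(self):
        d = fastqz_delta(ID1, ID1)
        assert (d.column, d.increment, d.match_len, d.literal) == \
            (0, 0, len(ID1), "")

    def test_increment_never_exceeds_255(self):
        # the exact field increment would be 299; a partial increment
        # (1 -> 30) still recovers two digits of copy before the literal
        d = fastqz_delta("r1", "r300")
        assert d.increment <= 255
        assert apply_line_delta("r1", d) == "r300"

    def test_no_admissible_increment_degrades_to_mismatch(self):
        d = fastqz_delta("rA", "r300")
        assert d.column == 0 and d.increment == 0
        assert apply_line_delta("rA", d) == "r300"

    def test_carry_over_digit_width(self):
        d = fastqz_delta("x99 tail", "x100tail")
        assert apply_line_delta("x99 tail", d) == "x100tail"

    def test_chosen_match_is_maximal_against_brute_force(self, rng):
        def brute(prev, cur):
            best = len(_common(prev, cur))
            for mo in __import__("re").finditer(r"[0-9]+", prev):
                start, end = mo.start(), mo.end()
                if end > 255:
                    continue
                v = int(mo.group(0))
                for inc in range(1, 256):
                    s2 = str(v + inc)
                    if len(s2) < end - start:
                        s2 = s2.zfill(end - start)
                    adj = prev[:start] + s2 + prev[end:]
                    best = max(best, min(len(_common(adj, cur)), 255))
            return best

        def _common(a, b):
            n = 0
            while n < min(len(a), len(b)) and a[n] == b[n]:
                n += 1
            return a[:n]

        for _ in range(60):
            prev = "".join(rng.choice("ab019 .:") for _ in range(rng.randrange(1, 40)))
            cur = "".join(rng.choice("ab019 .:") for _ in range(rng.randrange(1, 40)))
            d = fastqz_delta(prev, cur)
            assert d.match_len == min(brute(prev, cur), 255), (prev, cur)
            assert apply_line_delta(prev, d) == cur


@pytest.mark.parametrize("slow", [False, True])
def test_fastqz_id_stream_roundtrip(slow, rng):
    n = 120 if slow else 400
    ids = [f"@SRR.{i} inst:1:{rng.randrange(30)}:{rng.randrange(20000)}/1"
           for i in range(n)]
    enc = FastqzIdEncoder(slow)
    for i in ids:
        enc.add(i)
    data = enc.finish()
    dec = FastqzIdDecoder(data, slow)
    assert [dec.get() for _ in ids] == ids
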