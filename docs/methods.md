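# Methods

This note documents the models implemented in `fqzlite`, the constants
they use, the design choices made where the published descriptions of
the fqzcomp/fastqz/samcomp family leave the details open, and what the
synthetic data does and does not establish about behaviour on real
sequencing output.

## Coding engine

All codecs drive one byte-wise range coder (32-bit low/range, byte
renormalisation, carry propagation through a cached byte plus a pending
counter; the decoder skips one leading dummy byte and the encoder
flushes five tail bytes, so framing overhead is a constant ≤6 bytes per
stream). Two interfaces exist: a cumulative-frequency interface for
multi-symbol models and a binary interface driven by 12-bit
probabilities. Probabilities are clamped to [1/4096, 4095/4096] so no
symbol can cost unbounded bits.

**Direct models.** A `DirectContextModel` keeps 8-bit counters per
context; coding frequency is `count+1`, and when a counter would pass
255 all counters in that context are halved rounding up (ordering is
preserved, nonzero counts stay nonzero). The default increment is +4:
the steady-state probability quantisation of an increment-`i` model is
roughly `i / total`, and at +8 that alone costs ~1.6% excess on a
0.9-skewed source — more than the engine's whole 1%-of-entropy
optimality budget. Codecs whose statistics drift quickly (qualities,
per-coordinate consensus) pass larger increments explicitly.

**Indirect models.** A bit-history model maps a context hash to an
8-bit state — run length of the last bit, saturating at 40, 81 states
total — and the state to an adaptively updated probability shared
across contexts, so rare contexts borrow statistics from common history
patterns.

**Mixing.** Binary predictions are combined by weighted averaging in
the logistic domain: `p = squash(Σ wᵢ·stretch(pᵢ))` with
`stretch(p) = ln(p/(1−p))` and `squash` its inverse, both realised as
4096-entry integer tables (scale 256 per logit) so encoder and decoder
agree bit-for-bit on every platform. Weights live in 16.16 fixed point,
start at 1/n (agreeing inputs therefore reproduce themselves), are
selected per context, and update by an integer gradient step
`wᵢ += (stretchᵢ · err) >> 13`, equivalent to a learning rate of about
0.002 in the stretch domain.

**Secondary estimation and match model.** The SSE stage refines a
prediction by mixing it with a constant in the logistic domain, the
weight pair selected by a per-context bit history. The match model
hashes the last *n* coded bytes, remembers where that context last
occurred, and predicts the next bit of the remembered continuation with
probability 1 − 1/(match length in bits); one mispredicted bit cancels
the match.

## Identifiers

Tokenization splits an identifier into alpha, numeric,
leading-zero-numeric and punctuation runs (the zero prefix and the
remaining digits are separate tokens so `"0"` vs `"00"` round-trips).
Against the previous record, per-slot comparison yields MATCH tokens
for identical values and DELTA tokens for numeric fields that grew by
0–255; everything else is re-coded literally under per-slot models
(numeric values as four 8-bit little-endian models per 32-bit chunk
with a continuation bit for larger values). At most 32 token slots are
modelled; a record that tokenizes wider, or contains bytes outside
ASCII 32–126, falls back to string-delta coding (common-prefix length
plus literal suffix), which is also the preferred mode for 454-style
base-64 names whose token counts are unstable. An optional alphanumeric
token type (`[A-Za-z][A-Za-z0-9]*`) exists behind a flag, default off.

The fastqz-style line delta stores `(column)(increment)(copy)(literal)(0)`
where `column` is the 1-based position of the last digit of the decimal
run receiving the increment. Only the digit run covering the first
divergent byte can lengthen the copy (an increment always rewrites that
run's last digit), so the search tries the exact field difference
first — provably maximal when the copy runs past the rewritten digits —
and otherwise scans all 255 admissible increments, making the chosen
copy length maximal by construction. Increments above 255 are never
stored; if no admissible pair beats the plain common prefix the record
is coded as a mismatch (column 0). In slow mode the serialized records
are context-mixed bit-by-bit using two direct and two indirect models
over the last 1–4 bytes of the current line, the byte at the same
column of the previous line and the partial bits of the current byte,
with mixing weights selected by the column.

## Qualities

Phred+33 values map to canonical symbols: 0 is reserved for `N` base
calls, values clamp to 62, and a terminal run (length ≥ 2) of score 2 —
the Illumina failure tail — collapses to the sentinel 63. A single
trailing `2` is *not* collapsed, keeping the mapping unambiguous.
Because clamping and the `N↔0` convention can in principle lose
information on adversarial input, the container records per-record
exception lists (position, original byte) whenever the reconstruction
would differ, so lossless mode is byte-exact for *any* valid FASTQ, not
just convention-abiding files.

Context levels: (1) previous quality; (2) plus the second-previous
quality quantised by 4; (3) plus a position bucket (width 16, capped at
127), the maximum of the previous six qualities quantised by 8, and a
flag that any quality so far was below 20. Level 3 quantises its
components harder than level 2 quantises its own so that the richer key
does not dilute per-context statistics: with these widths level 3 is
never worse than level 1 beyond startup noise at the generator's
default data volume, while still expressing the three correlations
quality streams show (neighbour correlation, positional decline,
good/bad reads).

The fastqz path first packs symbols into byte codes — runs of score 38
up to length 55, triples in 35–38, pairs in 31–38, singles for
everything else, and an end-of-2s marker (247 of the 256 code points;
code 247 delimits records) — greedily preferring run > triple > pair >
single, then optionally context-mixes the code bytes with three direct
models (previous code; previous two codes; position bucket with
previous code).

Lossy modes: `fastqz_round` replaces every value above 1 with the
nearest multiple of Q (half rounds up; results clamp into [1, 62], so
the error stays ≤ ⌈Q/2⌉); `fqzcomp_within` replaces every value above Q
with the value inside ±Q whose current context count is highest, i.e.
the one that encodes to the fewest bits right now, tie-breaking toward
the original. Q = 1 is exactly lossless in both modes. Lossy mode also
enforces the `N↔quality-0` convention rather than recording exceptions.

## Sequence coding

The fqzcomp path codes A,C,G,T as 0–3 under an order-*k* model (2 bits
per base of context, register reset at each read start so records stay
independently decodable). `N` is coded as 0 and restored from its zero
quality during decompression. Options: additionally updating the
reverse-complement context on every observation (helps when per-strand
coverage is low), and a second fixed order-7 model with per-symbol
selection of whichever model currently holds the larger single-symbol
bias — decided by cross-multiplying maximum frequencies, ties to the
order-*k* model, so the decoder makes the identical choice. Levels:
k=12 (fast), k=14 (medium), k=16 with hashed contexts into 2²⁶ slots
plus reverse-complement update and the dual order-7 model (slow); hash
collisions cost ratio, never correctness.

The fastqz path packs bases with codes A=1, T=2, C=3, G=4:
three bases accumulate to `v = ((c₁·4)+c₂)·4+c₃ ∈ [21, 84]` and a
fourth is appended iff `v·4+c₄ ≤ 255`. Any group starting G, CG or CCG
therefore stays at three bases (bytes 64–84) — and so does CCC before a
G (byte 63), a corner the three-prefix description misses but the
arithmetic forces. Full-group bytes occupy 63–255; values 1–62 are
reserved for the terminal remainder of a read (1–4 one base, 5–20 two
bases, 21–62 a final three-base group), all decodable by the same
digit-expansion rule. The non-zero code offset makes the parse
self-synchronizing: shifted copies of the same sequence converge to the
same group boundaries, which is what lets the byte-level models find
repeats. In slow mode the packed bytes are coded bit-by-bit under a
mixer over direct order-0/1/2 models, an indirect order-3 model refined
by an order-4 SSE, and an order-5 match model.

## Reference-based coding (FASTQ)

The reference is packed 4 bases per byte (A=0,C=1,G=2,T=3; N runs
deleted but recorded) and divided into non-overlapping 32-base groups;
each group's 64-bit mixing hash selects a slot in a 2^b table (b=20 by
default, configurable) holding a pointer and a 5-bit checksum, with
linear probing over at most 8 slots; pointers that find no slot are
discarded — lost coverage, never an error. Alignment hashes every
32-base window of the read on both strands (reverse complement for the
minus strand), looks each up (at most 16 candidate evaluations per
strand), and ranks candidate windows by the position of the fourth
mismatch, ties broken by the third, second, first. A best fourth
mismatch before half the read length, a read shorter than 32 bases, or
a read longer than 254 bases (mismatch positions are single bytes)
codes as unmatched. Matched bases before the fourth mismatch are
deleted from the sequence stream; the recorded mismatches are coded in
a side stream under the reference base as context, and the tail from
the fourth mismatch onward plus whole unmatched reads go through the
ordinary order-k coder. Alignment records serialize as
`m₁..m₄, dir, ptr` (one 0 byte when unmatched); slow mode codes them
under a direct context model keyed by parse state, partial bits, and
the high 6 bits of the previous byte except for the two low pointer
bytes. Compression and decompression must see the same reference; the
container stores its CRC and refuses a mismatch.

## SAM coding

Both samcomp modes share side streams: qnames through the tokenizing
identifier coder, qualities through the level-2 quality coder, flags /
mapq / rname switches / position deltas (zig-zag varints) / CIGAR
strings through small adaptive models. Only qname, flag, rname, pos,
mapq, cigar, seq, qual are preserved; the header rides along verbatim
as an opaque block, and columns 7–9 are normalised to `*`,`0`,`0`.

**samcomp1** (position-sorted input, enforced): each base anchored by
the CIGAR to a reference coordinate is coded by that coordinate's own
4-counter model (increment +32, halving past 224 — consensus statistics are nearly
deterministic, so fast saturation is right; models are created on
first touch and the whole per-chromosome table is dropped when the
sorted stream moves on). With a reference the coordinate's model is
seeded with 16 counts on the reference base; without one it is seeded
from first-touch statistics keyed by the previous coordinate's
consensus call, and only once that context is informative (majority
fraction ≥ 0.55) — an uninformative uniform seed would dilute the model
and measurably widen the no-reference gap. Insertions and soft-clips
use their own order-2 models; unmapped records use an order-8 model.

**samcomp2** (any order): per aligned base a match/mismatch bit is
coded under a 16-bit shift register of recent match outcomes; on
mismatch the base is coded under the reference base as context. No
per-coordinate state exists, so memory is independent of genome length,
at the price of much weaker sequence coding on deep data. Without a
reference it degrades (with a warning) to order-8 coding of everything.

## Container

`FQZ1` magic; mode/level/lossy-Q/flags header; optional reference
CRC-32; then tagged blocks (`M`etadata JSON, `I`dentifiers, `S`equence,
`Q`ualities, `A`lignments/fields, `X` mismatch literals, `L`engths,
`H`eader), each framed as tag + 8-byte length + payload + CRC-32.
Corruption is reported, never silently decoded. Read lengths are stored
once when uniform, else as a delta-coded side stream. Per-stream
accounting (`stats`) is exact block arithmetic: a store-mode container
reports 8 bits per base and per quality by construction. Compression
and decompression are record-streaming; only model tables scale with
anything other than record size.

## Synthetic data

The generator emulates what the codecs exploit: an order-m Markov
genome (order 1, mildly skewed Dirichlet transitions by default;
optional duplicated segments for repeat structure), uniform read
sampling from both strands, substitution errors (0.5%), rare N calls
with quality 0, qualities starting near 38 and declining 0.06/base with
a per-read level shift (σ 2.5) and AR(1) noise (σ 2, ρ 0.7) giving the
lag-1 autocorrelation real instruments show, a 10% chance of a terminal
run of score-2 `#`s at the read's 3' end, incrementing Illumina-style
names (and a 454-style base-36 option), and a coordinate-sorted truth
SAM with correct CIGARs (optional soft-clip and single-indel
injection). One seed drives independent sub-generators per component,
so outputs are byte-reproducible and changing one knob does not perturb
the others. Default scale (100 kb genome, 30×, 100 bp) keeps the
medium-mode ratio in the 0.15–0.30 regime typical of deep Illumina
data while every test and the acceptance script finish in minutes on
one core.

What it does not emulate — platform-specific error profiles (454
homopolymers, colour space), duplicate reads, coverage biases, real
repeat families — bounds what passing tests show: round-tripping and
the *direction* of every comparison (reference < no-reference, deep <
shallow, name-sorted identifiers < position-sorted) transfer to real
data, but absolute ratios on real accessions depend on instrument
quality distributions and genome repeat content. One published figure
is knowably out of desk-scale reach for that reason: the ~6% of index
pointers discarded when indexing a human genome reflects exactly
repeated 32-mers overflowing their shared probe window; a
uniformly-hashed simulation at the same load (0.34) discards only
~0.05%, and the package's simulation reports what it measures.

## Numerical and degenerate-input choices

Integer-only coding paths (fixed-point mixer, table-driven logistic
maps) make containers deterministic across platforms and runs. Empty
files, empty identifiers, length-1 reads, reads of all-`N`, qualities
of `*` in SAM, and records violating the `N↔0` convention all
round-trip (the last via exception side-channels). Model tie-breaks are
fixed (order-k over order-7; smaller value on equal lossy cost;
first-seen candidate on equal alignment rank) so encoder and decoder
never diverge. The packing corner case CCC-before-G emits byte 63,
kept distinct from the 1–62 remainder region.
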