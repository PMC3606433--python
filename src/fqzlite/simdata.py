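"""Synthetic sequencing data with the statistics the codecs exploit.

The generator produces a genome (order-m Markov chain over ACGT with
optional repeat insertion), Illumina-style reads sampled from both
strands with substitution errors and occasional N calls, qualities that
start high and decline along the read with a per-read quality shift and
autocorrelated noise, terminal runs of score 2 ('#') on a fraction of
reads, structured incrementing identifiers, and a coordinate-sorted truth
SAM with correct CIGAR strings.

All randomness flows from one integer seed through independent
sub-generators per component, so e.g. changing the name template never
perturbs the base calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .samcodec import SamRecordLite

__all__ = ["SimProfile", "gen_genome", "gen_reads", "SimReads",
           "write_fasta", "write_fastq", "sam_header"]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class SimProfile:
    """Study conditions for the generator.

    Defaults describe a deeply sequenced small genome with Illumina-like
    qualities: the regime where context models, per-position models and
    reference coding all have something to learn.
    """
    genome_length: int = 100_000
    markov_order: int = 1
    repeat_fraction: float = 0.0
    coverage: float = 30.0
    read_length: int = 100
    read_length_range: tuple | None = None    # (lo, hi) for variable lengths
    substitution_rate: float = 0.005
    n_rate: float = 0.0005
    quality_start: float = 38.0
    quality_decline: float = 0.06             # per base
    quality_shift_sd: float = 2.5             # per-read level
    quality_noise_sd: float = 2.0
    quality_noise_rho: float = 0.7            # AR(1) autocorrelation
    terminal_run2_probability: float = 0.1
    both_strands: bool = True
    softclip_probability: float = 0.0
    softclip_max: int = 10
    indel_probability: float = 0.0
    name_style: str = "illumina"              # or "ls454"
    instrument: str = "HWI-EAS110"
    flowcell: str = "103327062"
    run_id: int = 62634
    lane: int = 6
    rname: str = "sim1"


@dataclass
class SimReads:
    """Generated reads plus their position-sorted alignment truth."""
    fastq: list          # (identifier, seq, qual) in sequencing order
    sam: list            # SamRecordLite, coordinate sorted
    rname: str


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def gen_genome(profile: SimProfile, seed: int) -> str:
    """Order-m Markov genome with optional duplicated segments."""
    n = profile.genome_length
    if n < 1:
        raise ValueError("genome_length must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    m = profile.markov_order
    if m == 0:
        seq = rng.integers(0, 4, size=n)
    else:
        nctx = 4 ** m
        # mildly skewed transition table, fixed by the seed
        trans = rng.dirichlet([5.0, 5.0, 5.0, 5.0], size=nctx)
        cum = np.cumsum(trans, axis=1)
        seq = np.empty(n, dtype=np.int64)
        ctx = 0
        u = rng.random(n)
        for i in range(n):
            row = cum[ctx]
            c = int(np.searchsorted(row, u[i], side="right"))
            c = min(c, 3)
            seq[i] = c
            ctx = (ctx * 4 + c) % nctx
    genome = "".join(_BASES[seq])
    if profile.repeat_fraction > 0 and n > 4000:
        target = int(profile.repeat_fraction * n)
        copied = 0
        g = list(genome)
        while copied < target:
            ln = int(rng.integers(500, 2000))
            src = int(rng.integers(0, n - ln))
            dst = int(rng.integers(0, n - ln))
            g[dst:dst + ln] = g[src:src + ln]
            copied += ln
        genome = "".join(g)
    return genome


def _make_names(n: int, profile: SimProfile, rng) -> list:
    names = []
    if profile.name_style == "ls454":
        # mixed alphanumeric base-36 well names, 454 style
        alpha = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        for i in range(n):
            v = 7919 * (i + 1) + int(rng.integers(0, 1 << 20))
            s = ""
            for _ in range(9):
                s = alpha[v % 36] + s
                v //= 36
            names.append(f"@{profile.instrument[:1]}{s}")
        return names
    tile = 1
    x = 1000
    for i in range(n):
        x += int(rng.integers(1, 30))
        if x > 19999:
            x = 1000
            tile += 1
        y = int(rng.integers(1, 99999))
        names.append(
            f"@SRR{profile.run_id:06d}.{i + 1} "
            f"{profile.instrument}_{profile.flowcell}:{profile.lane}:"
            f"{tile}:{x}:{y}/1")
    return names


def gen_reads(genome: str, profile: SimProfile, seed: int) -> SimReads:
    """Sample reads with errors and qualities; returns FASTQ + truth SAM."""
    ss = np.random.SeedSequence([seed, 1])
    r_pos, r_err, r_qual, r_name, r_misc = \
        [np.random.default_rng(c) for c in ss.spawn(5)]
    G = len(genome)
    if profile.read_length_range:
        lo, hi = profile.read_length_range
    else:
        lo = hi = profile.read_length
    if hi > G:
        raise ValueError("read_length exceeds genome_length")
    mean_len = (lo + hi) / 2
    n_reads = max(1, int(round(G * profile.coverage / mean_len)))
    lens = (np.full(n_reads, lo) if lo == hi
            else r_pos.integers(lo, hi + 1, size=n_reads))
    names = _make_names(n_reads, profile, r_name)

    # per-read quality machinery, fully vectorised over a padded matrix
    Lmax = int(lens.max())
    noise = r_qual.normal(0.0, profile.quality_noise_sd, size=(n_reads, Lmax))
    rho = profile.quality_noise_rho
    for j in range(1, Lmax):
        noise[:, j] += rho * noise[:, j - 1]
    shift = r_qual.normal(0.0, profile.quality_shift_sd, size=n_reads)
    posdecay = profile.quality_start - profile.quality_decline * np.arange(Lmax)
    qmat = np.clip(np.rint(posdecay[None, :] + shift[:, None] + noise),
                   1, 40).astype(np.int64)
    tail_mask = r_qual.random(n_reads) < profile.terminal_run2_probability
    tail_len = 2 + r_qual.geometric(0.25, size=n_reads)

    fastq = []
    sam = []
    for i in range(n_reads):
        L = int(lens[i])
        sc = 0
        cigar_ops = []
        if profile.softclip_probability and \
                r_misc.random() < profile.softclip_probability:
            sc = int(r_misc.integers(1, profile.softclip_max + 1))
        body = L - sc
        # optional single indel inside the aligned body
        ins_at = del_at = -1
        if profile.indel_probability and body > 10 and \
                r_misc.random() < profile.indel_probability:
            if r_misc.random() < 0.5:
                ins_at = int(r_misc.integers(1, body - 1))
            else:
                del_at = int(r_misc.integers(1, body - 1))
        ref_take = body - (1 if ins_at >= 0 else 0) + (1 if del_at >= 0 else 0)
        pos = int(r_pos.integers(0, G - ref_take + 1))
        window = genome[pos:pos + ref_take]
        # build the aligned portion in reference orientation
        if ins_at >= 0:
            extra = str(_BASES[int(r_err.integers(0, 4))])
            aligned = window[:ins_at] + extra + window[ins_at:]
            cigar_core = f"{ins_at}M1I{body - ins_at - 1}M"
        elif del_at >= 0:
            aligned = window[:del_at] + window[del_at + 1:]
            cigar_core = f"{del_at}M1D{body - del_at}M"
        else:
            aligned = window
            cigar_core = f"{body}M"
        clip = "".join(_BASES[r_misc.integers(0, 4, size=sc)]) if sc else ""
        reverse = bool(profile.both_strands and r_pos.integers(0, 2))
        # sequencing errors apply in read orientation
        read_ref_orient = clip + aligned          # soft clip leads in SAM
        seq_list = list(read_ref_orient)
        errs = np.nonzero(r_err.random(L) < profile.substitution_rate)[0]
        for e in errs:
            old = seq_list[e]
            choices = [b for b in "ACGT" if b != old]
            seq_list[e] = choices[int(r_err.integers(0, 3))]
        ns = np.nonzero(r_err.random(L) < profile.n_rate)[0]
        for e in ns:
            seq_list[e] = "N"
        sam_seq = "".join(seq_list)

        # qualities follow the sequencing direction: decline and terminal
        # '#' runs sit at the 3' end of the read as sequenced
        q = qmat[i, :L].copy()
        if tail_mask[i]:
            t = min(int(tail_len[i]), L)
            q[L - t:] = 2
        q_sam = q[::-1].copy() if reverse else q
        q_sam[[int(e) for e in ns]] = 0      # N positions (ref orientation)
        sam_qual = "".join(chr(int(v) + 33) for v in q_sam)

        if reverse:
            fq_seq = _revcomp(sam_seq)
            fq_qual = sam_qual[::-1]
            flag = 16
        else:
            fq_seq = sam_seq
            fq_qual = sam_qual
            flag = 0
        fastq.append((names[i], fq_seq, fq_qual))
        cigar = (f"{sc}S" if sc else "") + cigar_core
        sam.append(SamRecordLite(
            qname=names[i].split()[0][1:], flag=flag, rname=profile.rname,
            pos=pos + 1, mapq=60, cigar=cigar, seq=sam_seq, qual=sam_qual))
    sam.sort(key=lambda r: r.pos)
    return SimReads(fastq, sam, profile.rname)


def sam_header(genome_len: int, rname: str = "sim1") -> str:
    return (f"@HD\tVN:1.6\tSO:coordinate\n"
            f"@SQ\tSN:{rname}\tLN:{genome_len}\n")


def write_fasta(path: str, genome: str, name: str = "sim1") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    SeqIO.write([SeqRecord(Seq(genome), id=name, description="")],
                path, "fasta")


def write_fastq(path: str, records, plus_id: bool = False) -> None:
    with open(path, "w") as fh:
        for ident, seq, qual in records:
            fh.write(f"{ident}\n{seq}\n")
            fh.write(f"+{ident[1:]}\n" if plus_id else "+\n")
            fh.write(f"{qual}\n")
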