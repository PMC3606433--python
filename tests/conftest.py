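import random

import pytest

from fqzlite.simdata import SimProfile, gen_genome, gen_reads


@pytest.fixture(scope="session")
def small_sim():
    """A 10 kb genome at 10x coverage with default error/quality structure."""
    prof = SimProfile(genome_length=10_000, coverage=10.0,
                      n_rate=0.002, terminal_run2_probability=0.15)
    genome = gen_genome(prof, 7)
    reads = gen_reads(genome, prof, 7)
    return prof, genome, reads


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free reads from a 10 kb genome (for reference-coding tests)."""
    prof = SimProfile(genome_length=10_000, coverage=8.0,
                      substitution_rate=0.001, n_rate=0.0,
                      terminal_run2_probability=0.0)
    genome = gen_genome(prof, 11)
    reads = gen_reads(genome, prof, 11)
    return prof, genome, reads


@pytest.fixture()
def rng():
    return random.Random(1234)


def random_fastq_records(rng, n, maxlen=60, n_prob=0.05, hash_tail_prob=0.3):
    """Arbitrary-but-valid FASTQ records exercising codec corner cases."""
    recs = []
    for i in range(n):
        L = rng.randrange(1, maxlen + 1)
        seq = "".join(rng.choice("ACGTN" if rng.random() < n_prob else "ACGT")
                      for _ in range(L))
        qual = []
        for j, b in enumerate(seq):
            if b == "N":
                qual.append("!")
            else:
                qual.append(chr(33 + rng.randrange(1, 42)))
        if rng.random() < hash_tail_prob and L >= 3:
            k = rng.randrange(2, min(L, 8))
            tail = []
            for j in range(L - k, L):
                tail.append("!" if seq[j] == "N" else "#")
            qual[L - k:] = tail
        ident = f"@r{i}.{rng.randrange(1000)} x:{rng.randrange(99)}:y/{1 + i % 2}"
        recs.append((ident, seq, "".join(qual)))
    return recs
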