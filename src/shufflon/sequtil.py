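"""Small DNA sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of ``length`` drawn from ``rng``."""
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def iter_kmers(seq: str, k: int):
    """Yield ``(position, kmer)`` for every length-k window of ``seq``."""
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes (A,C,G,T -> 0..3; anything else -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
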