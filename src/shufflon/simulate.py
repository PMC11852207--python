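"""Synthetic data: shuffled libraries, noisy long reads, planted repeats.

All randomness flows from explicit integer seeds; child generators are
derived with fixed offsets so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .design import Configuration, DesignError, ShufflonDesign
from .combinatorics import InversionEvent, apply_inversion, valid_events
from .sequtil import BASES, canonical_kmer, random_dna, revcomp

__all__ = [
    "ErrorModel",
    "LibrarySpec",
    "FastqRecord",
    "simulate_library",
    "simulate_reads",
    "plant_repeats",
    "positional_bias_weights",
    "write_fastq",
    "read_fastq",
    "write_truth",
]

_MAX_RATE = 0.2


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. substitution / insertion / deletion probabilities."""

    sub_rate: float = 0.02
    ins_rate: float = 0.02
    del_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= _MAX_RATE:
                raise DesignError(f"{name} must be in [0, {_MAX_RATE}], got {r}")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


@dataclass(frozen=True)
class LibrarySpec:
    """How to grow a shuffled plasmid library.

    Each member starts at the reference configuration and receives
    ``k ~ Poisson(event_rate)`` inversion events (or exactly
    ``fixed_events`` when set), sampled by weight and applied sequentially.
    """

    n_members: int
    event_rate: float = 1.0
    event_weights: Optional[Dict[InversionEvent, float]] = None
    seed: int = 0
    fixed_events: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise DesignError(f"n_members must be >= 1, got {self.n_members}")
        if self.event_rate < 0:
            raise DesignError(f"event_rate must be >= 0, got {self.event_rate}")


class FastqRecord(NamedTuple):
    id: str
    sequence: str
    quality: str


def positional_bias_weights(n: int, terminal_factor: float = 0.25) -> Dict[InversionEvent, float]:
    """Down-weight events touching the terminal junctions (0 and n).

    Mimics the observed bias that terminal modules shuffle less often than
    central ones.
    """
    return {ev: (terminal_factor if ev.site_i == 0 or ev.site_j == n else 1.0)
            for ev in valid_events(n)}


def simulate_library(n_or_design, spec: LibrarySpec) -> List[Configuration]:
    """Draw ``spec.n_members`` configurations under the inversion-event model."""
    n = n_or_design.n if isinstance(n_or_design, ShufflonDesign) else int(n_or_design)
    events = valid_events(n)
    if spec.event_weights is None:
        probs = np.full(len(events), 1.0 / len(events))
    else:
        w = np.array([float(spec.event_weights.get(ev, 0.0)) for ev in events])
        if np.any(w < 0) or w.sum() <= 0:
            raise DesignError("event weights must be non-negative and not all zero")
        probs = w / w.sum()
    rng = np.random.default_rng(spec.seed)
    if spec.fixed_events is not None:
        counts = np.full(spec.n_members, spec.fixed_events, dtype=np.int64)
    else:
        counts = rng.poisson(spec.event_rate, size=spec.n_members)
    members: List[Configuration] = []
    ref = Configuration.reference(n)
    for k in counts:
        cfg = ref
        if k:
            for ei in rng.choice(len(events), size=int(k), p=probs):
                cfg = apply_inversion(cfg, events[ei])
        members.append(cfg)
    return members


def _mutate(codes: np.ndarray, model: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    """Apply per-base substitutions, deletions, then insertions at gaps."""
    L = len(codes)
    out = codes.copy()
    sub_mask = rng.random(L) < model.sub_rate
    n_sub = int(sub_mask.sum())
    if n_sub:
        out[sub_mask] = (out[sub_mask] + rng.integers(1, 4, size=n_sub, dtype=np.uint8)) % 4
    keep = rng.random(L) >= model.del_rate
    out = out[keep]
    m = len(out)
    ins_mask = rng.random(m + 1) < model.ins_rate
    idx = np.flatnonzero(ins_mask)
    if len(idx):
        ins_bases = rng.integers(0, 4, size=len(idx), dtype=np.uint8)
        out = np.insert(out, idx, ins_bases)
    return out


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def simulate_reads(
    sources: Sequence[Tuple[str, str]],
    model: ErrorModel = ErrorModel(),
    depth: int = 1,
    seed: int = 0,
) -> List[FastqRecord]:
    """Noisy reads from ``(source_id, sequence)`` templates.

    Each template yields ``depth`` reads with i.i.d. per-base errors; each
    read is reverse-complemented with probability 0.5 (random sequencing
    orientation).  Read ids are ``r<index>|<source_id>`` so the true source
    (e.g. a configuration string) is recoverable; qualities are placeholder.
    """
    from .sequtil import encode

    rng = np.random.default_rng(seed)
    reads: List[FastqRecord] = []
    counter = 0
    for source_id, seq in sources:
        codes = encode(seq)
        for _ in range(depth):
            mutated = _mutate(codes, model, rng)
            read_seq = _decode(mutated)
            if rng.random() < 0.5:
                read_seq = revcomp(read_seq)
            reads.append(FastqRecord(f"r{counter:06d}|{source_id}", read_seq, "I" * len(read_seq)))
            counter += 1
    return reads


def plant_repeats(
    background_length: int,
    k: int = 13,
    positions: Sequence[int] = (),
    strands: Sequence[str] = (),
    seed: int = 0,
    kmer: Optional[str] = None,
) -> Tuple[str, str]:
    """Random background with a k-mer planted at chosen positions.

    ``strands[i]`` is ``'+'`` to write the k-mer itself at ``positions[i]``
    and ``'-'`` for its reverse complement.  The background is screened so
    that, apart from the planted copies, it contains no repeated k-mer at
    all (direct or inverted) — making the fixture's repeat content exactly
    the planted one.  Returns ``(sequence, kmer)``.
    """
    if len(positions) != len(strands):
        raise DesignError("positions and strands must have equal length")
    spans = sorted((p, p + k) for p in positions)
    for (a, b), (c, _) in zip(spans, spans[1:]):
        if c < b:
            raise DesignError("planted occurrences must not overlap")
    if spans and (spans[0][0] < 0 or spans[-1][1] > background_length):
        raise DesignError("planted occurrence out of bounds")
    rng = np.random.default_rng(seed)
    if kmer is None:
        kmer = random_dna(rng, k)
    elif len(kmer) != k:
        raise DesignError(f"kmer must have length {k}")

    seq = list(random_dna(rng, background_length))
    for pos, strand in zip(positions, strands):
        piece = kmer if strand == "+" else revcomp(kmer)
        seq[pos:pos + k] = piece
    planted = set(positions)
    protected = [False] * background_length
    for p in positions:
        for t in range(p, p + k):
            protected[t] = True

    # mutate unprotected bases until no unplanned repeated canonical k-mer remains
    for _ in range(10000):
        table: Dict[str, List[int]] = {}
        for i in range(background_length - k + 1):
            w = "".join(seq[i:i + k])
            table.setdefault(canonical_kmer(w), []).append(i)
        offending = None
        for canon, occ in table.items():
            if canon == canonical_kmer(kmer):
                extra = [i for i in occ if i not in planted]
                if extra:
                    offending = extra[0]
                    break
            elif len(occ) > 1:
                offending = occ[-1]
                break
        if offending is None:
            return "".join(seq), kmer
        free = [t for t in range(offending, offending + k) if not protected[t]]
        if not free:  # overlapping a planted span entirely; should not happen
            raise DesignError("cannot screen background without touching a planted copy")
        t = free[int(rng.integers(len(free)))]
        seq[t] = BASES[(BASES.index(seq[t]) + int(rng.integers(1, 4))) % 4]
    raise DesignError("background screening did not converge; try another seed")


# ---------------------------------------------------------------------------
# FASTQ / truth-table I/O
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[FastqRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path) -> List[FastqRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_truth(reads: Iterable[FastqRecord], path) -> None:
    """TSV of read id to true source id (the part after the first '|')."""
    with open(path, "w") as fh:
        fh.write("read_id\tsource_id\n")
        for r in reads:
            source = r.id.split("|", 1)[1] if "|" in r.id else ""
            fh.write(f"{r.id}\t{source}\n")
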