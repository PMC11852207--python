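"""k-mer repeat mining in flanking DNA and candidate-site reconstruction.

The screen looks for 13-mers that occur multiple times on one strand
(direct repeats) or at least twice as inverted repeats, reconstructs
31-nt candidate recombination sites around each occurrence, and applies
novelty (exact match to known k-mers) and palindromy (left arm vs
reverse-complemented right arm) filters.

Occurrences are recorded on the forward strand, canonicalized by the
lexicographic minimum of k-mer and reverse complement; overlapping
occurrences are counted.  Windows containing N never match.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .design import DesignError, SITE_LEN
from .sequtil import canonical_kmer, revcomp

__all__ = [
    "FlankRecord",
    "RepeatHit",
    "CandidateSite",
    "find_repeats",
    "classify_locus",
    "novelty_filter",
    "reconstruct_sites",
    "pick_representative_site",
    "mine_fasta",
    "DEFAULT_K",
    "DEFAULT_OFFSET",
    "PALINDROMY_THRESHOLD",
]

DEFAULT_K = 13
#: Default register of the conserved k-mer inside the 31-nt window: flush
#: with the right end (the conserved core + right arm region).
DEFAULT_OFFSET = SITE_LEN - DEFAULT_K
PALINDROMY_THRESHOLD = 0.75

CATEGORY_NONE = "no_repeat"
CATEGORY_DIRECT = "direct_only"
CATEGORY_BOTH = "direct_and_inverted"


@dataclass(frozen=True)
class FlankRecord:
    """Concatenated flanking DNA of one candidate locus."""

    locus_id: str
    sequence: str
    note: str = ""

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise DesignError(f"locus {self.locus_id}: sequence must be non-empty A/C/G/T/N")


@dataclass(frozen=True)
class RepeatHit:
    """All occurrences of one canonical k-mer in a locus.

    ``occurrences`` are ``(position, strand)`` with 0-based forward-strand
    positions, sorted by position; strand is '+' when the window equals the
    canonical k-mer, '-' when it equals its reverse complement.
    """

    canonical_kmer: str
    occurrences: Tuple[Tuple[int, str], ...]
    n_direct: int
    n_inverted_pairs: int
    novel: bool = True


@dataclass(frozen=True)
class CandidateSite:
    """A reconstructed 31-nt candidate site around one k-mer occurrence."""

    window: str
    position: int
    strand: str
    palindromy_score: float
    novel: bool = True

    @property
    def left_arm(self) -> str:
        return self.window[:12]

    @property
    def core(self) -> str:
        return self.window[12:19]

    @property
    def right_arm(self) -> str:
        return self.window[19:]


def find_repeats(record: FlankRecord, k: int = DEFAULT_K) -> List[RepeatHit]:
    """Exhaustive sliding-window repeat screen of one locus.

    A canonical k-mer is reported iff it has at least two occurrences on a
    single strand, or at least one opposite-strand pair.
    """
    seq = record.sequence
    if len(seq) < k:
        warnings.warn(f"locus {record.locus_id}: sequence shorter than k={k}")
        return []
    table: Dict[str, List[Tuple[int, str]]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "N" in w:
            continue
        canon = canonical_kmer(w)
        table[canon].append((i, "+" if w == canon else "-"))
    hits = []
    for canon in sorted(table):
        occ = table[canon]
        plus = sum(1 for _, s in occ if s == "+")
        minus = len(occ) - plus
        n_direct = max(plus, minus)
        n_inverted = min(plus, minus)
        if n_direct >= 2 or n_inverted >= 1:
            hits.append(RepeatHit(canon, tuple(sorted(occ)), n_direct, n_inverted))
    return hits


def classify_locus(hits: Sequence[RepeatHit]) -> str:
    """Categorize a locus from its repeat hits."""
    if any(h.n_inverted_pairs >= 1 for h in hits):
        return CATEGORY_BOTH
    if any(h.n_direct >= 2 for h in hits):
        return CATEGORY_DIRECT
    return CATEGORY_NONE


def novelty_filter(hits: Sequence[RepeatHit], known_kmers: Iterable[str]) -> List[RepeatHit]:
    """Flag hits whose canonical k-mer matches a known k-mer (either strand).

    Nothing is removed; hits are returned with ``novel`` set accordingly.
    """
    known = {canonical_kmer(km.upper()) for km in known_kmers}
    return [replace(h, novel=h.canonical_kmer not in known) for h in hits]


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reconstruct_sites(
    record: FlankRecord,
    hit: RepeatHit,
    offset: int = DEFAULT_OFFSET,
) -> List[CandidateSite]:
    """31-nt candidate windows around each occurrence of a hit.

    The window is taken so that the canonical k-mer sits at ``offset``
    within it; minus-strand occurrences are reverse-complemented so that
    right arms align across occurrences.  Windows truncated by the
    sequence ends are dropped.
    """
    k = len(hit.canonical_kmer)
    if not 0 <= offset <= SITE_LEN - k:
        raise DesignError(f"offset must be in [0, {SITE_LEN - k}]")
    seq = record.sequence
    sites = []
    for pos, strand in hit.occurrences:
        if strand == "+":
            start = pos - offset
        else:
            start = pos - (SITE_LEN - k - offset)
        if start < 0 or start + SITE_LEN > len(seq):
            continue
        window = seq[start:start + SITE_LEN]
        if strand == "-":
            window = revcomp(window)
        score = _identity(window[:12], revcomp(window[19:]))
        sites.append(CandidateSite(window, pos, strand, score, novel=hit.novel))
    if not sites:
        warnings.warn(f"locus {record.locus_id}: all {SITE_LEN}-nt windows truncated")
    return sites


def pick_representative_site(
    sites: Sequence[CandidateSite],
    palindromy_threshold: float = PALINDROMY_THRESHOLD,
    seed: int = 0,
) -> CandidateSite:
    """Pick one site per locus: modal left arm, seeded random tie-break.

    Sites whose left arm is (near-)palindromic with the right arm are
    excluded first; if every site is palindromic the locus is rejected,
    mirroring the exclusion of symmetric candidate sites.
    """
    usable = [s for s in sites if s.palindromy_score < palindromy_threshold]
    if not usable:
        raise DesignError("all candidate sites are palindromic; locus excluded")
    counts: Dict[str, int] = defaultdict(int)
    for s in usable:
        counts[s.left_arm] += 1
    top = max(counts.values())
    tied = sorted(arm for arm, c in counts.items() if c == top)
    rng = np.random.default_rng(seed)
    arm = tied[int(rng.integers(len(tied)))] if len(tied) > 1 else tied[0]
    return next(s for s in usable if s.left_arm == arm)


# ---------------------------------------------------------------------------
# File-level driver
# ---------------------------------------------------------------------------

def mine_fasta(
    fasta_path,
    known_kmers: Iterable[str] = (),
    k: int = DEFAULT_K,
    offset: int = DEFAULT_OFFSET,
    palindromy_threshold: float = PALINDROMY_THRESHOLD,
    seed: int = 0,
):
    """Run the full screen on a multi-FASTA of flanking regions.

    Returns ``(per_locus, representatives, summary)`` where ``per_locus``
    maps locus id to ``(category, hits)``, ``representatives`` maps locus
    id to its chosen :class:`CandidateSite` (novel, non-palindromic loci
    with inverted repeats only), and ``summary`` counts loci per category.
    """
    from Bio import SeqIO

    per_locus = {}
    representatives = {}
    known = list(known_kmers)
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        record = FlankRecord(rec.id, str(rec.seq).upper())
        hits = novelty_filter(find_repeats(record, k=k), known)
        category = classify_locus(hits)
        per_locus[record.locus_id] = (category, hits)
        if category != CATEGORY_BOTH:
            continue
        novel_inverted = [h for h in hits if h.n_inverted_pairs >= 1 and h.novel]
        for hit in novel_inverted:
            sites = reconstruct_sites(record, hit, offset=offset)
            try:
                representatives[record.locus_id] = pick_representative_site(
                    sites, palindromy_threshold=palindromy_threshold, seed=seed)
                break
            except DesignError:
                continue
    summary = {CATEGORY_NONE: 0, CATEGORY_DIRECT: 0, CATEGORY_BOTH: 0}
    for category, _ in per_locus.values():
        summary[category] += 1
    summary["representative_sites"] = len(representatives)
    return per_locus, representatives, summary


def write_mine_outputs(per_locus, representatives, summary, outdir) -> None:
    """Write the TSV / FASTA / JSON outputs of :func:`mine_fasta`."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "loci.tsv", "w") as fh:
        fh.write("locus_id\tcategory\tcanonical_kmer\tn_direct\tn_inverted_pairs\tnovel\toccurrences\n")
        for locus_id, (category, hits) in per_locus.items():
            if not hits:
                fh.write(f"{locus_id}\t{category}\t\t0\t0\t\t\n")
            for h in hits:
                occ = ",".join(f"{p}{s}" for p, s in h.occurrences)
                fh.write(f"{locus_id}\t{category}\t{h.canonical_kmer}\t{h.n_direct}"
                         f"\t{h.n_inverted_pairs}\t{h.novel}\t{occ}\n")
    with open(outdir / "candidate_sites.fasta", "w") as fh:
        for locus_id, site in representatives.items():
            fh.write(f">{locus_id} left_arm={site.left_arm} core={site.core} "
                     f"right_arm={site.right_arm} palindromy={site.palindromy_score:.2f}\n")
            fh.write(site.window + "\n")
    with open(outdir / "mine_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
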