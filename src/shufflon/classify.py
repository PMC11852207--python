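"""Decode long reads into shufflon configurations.

Two decoders are provided:

- the production *marker* decoder: exact k-mer markers unique to each
  module (and to the anchors, for global orientation) are located on the
  read; modules are ordered by their median marker position and oriented
  by the majority marker strand;
- the *exhaustive* decoder, the faithful slow oracle: the read's shuffled
  core is localized via the anchors and its edit distance to every
  rendered reference core is computed; the unique minimizer wins if its
  identity clears a floor, and any tie is left unclassified.

Both are pure functions of (read, design, parameters); failures are
statuses, never exceptions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .design import Configuration, DesignError, ShufflonDesign, render_reference_set
from .sequtil import encode, iter_kmers, revcomp
from . import _myers

__all__ = [
    "ReadRecord",
    "ClassificationResult",
    "MarkerIndex",
    "ExhaustiveDecoder",
    "size_filter",
    "build_marker_index",
    "classify_read",
    "classify_read_exhaustive",
    "classify_reads",
    "summarize",
    "write_results_tsv",
]

STATUS_CLASSIFIED = "classified"
STATUS_UNCLASSIFIED = "unclassified"
STATUS_SIZE_FILTERED = "size_filtered"


@dataclass(frozen=True)
class ReadRecord:
    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DesignError(f"read {self.id}: empty sequence")


@dataclass(frozen=True)
class ClassificationResult:
    read_id: str
    status: str
    configuration: Optional[Configuration] = None
    score: float = 0.0
    global_strand: str = "+"
    reason: str = ""

    def __post_init__(self) -> None:
        if (self.configuration is not None) != (self.status == STATUS_CLASSIFIED):
            raise DesignError("configuration must be present iff status is classified")


def size_filter(
    reads: Sequence[ReadRecord],
    expected_length: int,
    tolerance_fraction: float = 0.15,
) -> Tuple[List[ReadRecord], List[ClassificationResult]]:
    """Split reads into those within the size band and size-filtered results.

    A read passes iff ``abs(len - expected) <= tolerance * expected``.
    """
    if not 0.0 < tolerance_fraction < 1.0:
        raise DesignError("tolerance_fraction must be in (0, 1)")
    passed: List[ReadRecord] = []
    rejected: List[ClassificationResult] = []
    band = tolerance_fraction * expected_length
    for read in reads:
        if abs(len(read.sequence) - expected_length) <= band:
            passed.append(read)
        else:
            rejected.append(ClassificationResult(
                read.id, STATUS_SIZE_FILTERED,
                reason=f"length {len(read.sequence)} outside {expected_length}+/-{band:.0f}"))
    return passed, rejected


# ---------------------------------------------------------------------------
# Marker decoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerIndex:
    """Exact k-mer markers unique across the whole construct (both strands).

    ``module_markers[kmer] = (module_id, offset, strand)`` where strand is
    '+' if the k-mer reads off the module's forward sequence; offset is the
    k-mer start within that strand's sequence.  ``anchor_markers[kmer]``
    is '+'/'-' for k-mers of the anchors used to call global orientation.
    """

    k: int
    module_markers: Dict[str, Tuple[int, int, str]]
    anchor_markers: Dict[str, str]
    per_module_counts: Dict[int, int]


def build_marker_index(design: ShufflonDesign, k: int = 15, min_markers: int = 10) -> MarkerIndex:
    """Collect k-mers that occur exactly once across modules, anchors and
    site (on either strand) and attribute them to their source."""
    sources: Dict[str, List[Tuple[str, int, int, str]]] = defaultdict(list)
    # kind, ident, offset, strand
    components: List[Tuple[str, int, str]] = []
    for m in design.modules:
        components.append(("module", m.id, m.sequence))
    components.append(("anchor", 0, design.anchor_left))
    components.append(("anchor", 1, design.anchor_right))
    components.append(("site", 0, design.site.sequence))
    for kind, ident, seq in components:
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for off, km in iter_kmers(s, k):
                sources[km].append((kind, ident, off, strand))

    module_markers: Dict[str, Tuple[int, int, str]] = {}
    anchor_markers: Dict[str, str] = {}
    for km, occ in sources.items():
        if len(occ) != 1:
            continue
        kind, ident, off, strand = occ[0]
        if kind == "module":
            module_markers[km] = (ident, off, strand)
        elif kind == "anchor":
            anchor_markers[km] = strand
    counts = Counter(mid for mid, _, strand in module_markers.values() if strand == "+")
    per_module = {m.id: counts.get(m.id, 0) for m in design.modules}
    lacking = [mid for mid, c in per_module.items() if c < min_markers]
    if lacking:
        raise DesignError(
            f"modules {lacking} have fewer than {min_markers} unique {k}-mers; "
            "increase k or redesign the modules")
    return MarkerIndex(k, module_markers, anchor_markers, per_module)


def _scan(sequence: str, index: MarkerIndex):
    anchor_votes = Counter()
    module_hits: Dict[int, List[Tuple[int, str]]] = defaultdict(list)
    k = index.k
    for i in range(len(sequence) - k + 1):
        km = sequence[i:i + k]
        strand = index.anchor_markers.get(km)
        if strand is not None:
            anchor_votes[strand] += 1
            continue
        hit = index.module_markers.get(km)
        if hit is not None:
            mid, _off, strand = hit
            module_hits[mid].append((i, strand))
    return anchor_votes, module_hits


def classify_read(
    read: ReadRecord,
    index: MarkerIndex,
    design: ShufflonDesign,
    min_score: float = 0.6,
    min_hits: int = 3,
) -> ClassificationResult:
    """Marker-based decoding of one read.

    Global strand is called from anchor-marker votes and the read is
    canonicalized; each module is then located by the median position of
    its marker hits and oriented by their majority strand.  The call is
    rejected (status ``unclassified``) unless every module is found, the
    arrangement is parity-valid, and the fraction of orientation-consistent
    marker hits reaches ``min_score``.
    """
    seq = read.sequence.upper()
    anchor_votes, module_hits = _scan(seq, index)
    if not anchor_votes:
        return ClassificationResult(read.id, STATUS_UNCLASSIFIED, reason="no anchor markers")
    global_strand = "+"
    if anchor_votes["-"] > anchor_votes["+"]:
        global_strand = "-"
        seq = revcomp(seq)
        _, module_hits = _scan(seq, index)

    placements: List[Tuple[float, int, int]] = []  # (median pos, signed id, n hits)
    total_hits = 0
    consistent_hits = 0
    for m in design.modules:
        hits = module_hits.get(m.id, [])
        if len(hits) < min_hits:
            return ClassificationResult(
                read.id, STATUS_UNCLASSIFIED, global_strand=global_strand,
                reason=f"module {m.id}: {len(hits)} marker hits < {min_hits}")
        votes = Counter(strand for _, strand in hits)
        if votes["+"] == votes["-"]:
            return ClassificationResult(
                read.id, STATUS_UNCLASSIFIED, global_strand=global_strand,
                reason=f"module {m.id}: orientation tie")
        orient = 1 if votes["+"] > votes["-"] else -1
        total_hits += len(hits)
        consistent_hits += votes["+" if orient > 0 else "-"]
        placements.append((median(p for p, _ in hits), orient * m.id, len(hits)))

    placements.sort(key=lambda t: t[0])
    config = Configuration(tuple(signed for _, signed, _ in placements))
    if not config.is_valid():
        return ClassificationResult(
            read.id, STATUS_UNCLASSIFIED, global_strand=global_strand,
            reason=f"decoded order {config.to_string()} violates parity")
    score = consistent_hits / total_hits if total_hits else 0.0
    if score < min_score:
        return ClassificationResult(
            read.id, STATUS_UNCLASSIFIED, global_strand=global_strand,
            reason=f"marker consistency {score:.2f} < {min_score}")
    return ClassificationResult(read.id, STATUS_CLASSIFIED, configuration=config,
                                score=score, global_strand=global_strand)


# ---------------------------------------------------------------------------
# Exhaustive (oracle) decoder
# ---------------------------------------------------------------------------

class ExhaustiveDecoder:
    """Edit-distance classification against every rendered reference.

    The anchors are constant across references, so the read's shuffled core
    is first localized with 192-bp anchor probes; the core's Levenshtein
    distance to each reference core is then computed exactly.  A read is
    classified iff a unique minimum exists and its identity
    ``1 - d / max(len)`` reaches ``identity_floor``; ties are always left
    unclassified, since arbitrary assignment would inflate diversity.
    """

    PROBE_LEN = 192  # multiple of 64, required by the bit-parallel search

    def __init__(
        self,
        design: ShufflonDesign,
        reference_set: Optional[Dict[str, str]] = None,
        identity_floor: float = 0.80,
        max_probe_errors: float = 0.30,
    ) -> None:
        if len(design.anchor_left) < self.PROBE_LEN or len(design.anchor_right) < self.PROBE_LEN:
            raise DesignError(f"anchors must be at least {self.PROBE_LEN} bp for the oracle")
        self.design = design
        self.identity_floor = identity_floor
        self.max_probe_errors = max_probe_errors
        refs = reference_set if reference_set is not None else render_reference_set(design)
        start, end = design.core_span()
        self.configs = list(refs.keys())
        cores = [seq[start:end] for seq in refs.values()]
        self.core_len = end - start
        self._core_codes = np.vstack([encode(c) for c in cores])
        self._probe_left = design.anchor_left[-self.PROBE_LEN:]
        self._probe_right_rc = revcomp(design.anchor_right[:self.PROBE_LEN])

    def _orient(self, seq: str) -> Tuple[str, str, int, int]:
        fwd_score, fwd_end = _myers.locate(self._probe_left, seq)
        rc = revcomp(seq)
        rev_score, rev_end = _myers.locate(self._probe_left, rc)
        if fwd_score <= rev_score:
            return seq, "+", fwd_end, fwd_score
        return rc, "-", rev_end, rev_score

    def classify(self, read: ReadRecord) -> ClassificationResult:
        seq, strand, core_start, left_score = self._orient(read.sequence.upper())
        limit = self.max_probe_errors * self.PROBE_LEN
        right_score, right_end = _myers.locate(self._probe_right_rc, revcomp(seq))
        if left_score > limit or right_score > limit:
            return ClassificationResult(read.id, STATUS_UNCLASSIFIED, global_strand=strand,
                                        reason="anchor probes not found")
        core_end = len(seq) - right_end
        if core_end <= core_start:
            return ClassificationResult(read.id, STATUS_UNCLASSIFIED, global_strand=strand,
                                        reason="empty core after anchor localization")
        core = seq[core_start:core_end]
        dists = _myers.batch_edit_distance(core, self._core_codes)
        best = int(dists.min())
        winners = np.flatnonzero(dists == best)
        if len(winners) > 1:
            return ClassificationResult(read.id, STATUS_UNCLASSIFIED, global_strand=strand,
                                        reason=f"tie at distance {best} between "
                                               f"{len(winners)} references")
        identity = 1.0 - best / max(len(core), self.core_len)
        if identity < self.identity_floor:
            return ClassificationResult(read.id, STATUS_UNCLASSIFIED, global_strand=strand,
                                        reason=f"identity {identity:.3f} < {self.identity_floor}")
        config = Configuration.from_string(self.configs[int(winners[0])])
        return ClassificationResult(read.id, STATUS_CLASSIFIED, configuration=config,
                                    score=identity, global_strand=strand)


def classify_read_exhaustive(
    read: ReadRecord,
    decoder_or_design,
    reference_set: Optional[Dict[str, str]] = None,
    identity_floor: float = 0.80,
) -> ClassificationResult:
    """Functional wrapper around :class:`ExhaustiveDecoder`."""
    if isinstance(decoder_or_design, ExhaustiveDecoder):
        return decoder_or_design.classify(read)
    decoder = ExhaustiveDecoder(decoder_or_design, reference_set, identity_floor)
    return decoder.classify(read)


# ---------------------------------------------------------------------------
# Batch helpers
# ---------------------------------------------------------------------------

def classify_reads(
    reads: Sequence[ReadRecord],
    index: MarkerIndex,
    design: ShufflonDesign,
    expected_length: Optional[int] = None,
    tolerance_fraction: float = 0.15,
    min_score: float = 0.6,
    min_hits: int = 3,
) -> List[ClassificationResult]:
    """Size-filter then marker-classify a batch of reads."""
    expected = expected_length if expected_length is not None else design.total_length
    passed, results = size_filter(reads, expected, tolerance_fraction)
    for read in passed:
        results.append(classify_read(read, index, design, min_score=min_score,
                                     min_hits=min_hits))
    return results


def summarize(results: Iterable[ClassificationResult], design_id: str = "shufflon"):
    """Aggregate per-read results into a :class:`~shufflon.stats.LibrarySummary`."""
    from .stats import LibrarySummary

    counts: Dict[str, int] = Counter()
    n_unclassified = 0
    for res in results:
        if res.status == STATUS_CLASSIFIED:
            counts[res.configuration.to_string()] += 1
        else:
            n_unclassified += 1
    return LibrarySummary(design_id=design_id, counts=dict(counts),
                          n_unclassified=n_unclassified)


def write_results_tsv(results: Iterable[ClassificationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstatus\tconfiguration\tscore\tstrand\treason\n")
        for r in results:
            cfg = r.configuration.to_string() if r.configuration is not None else ""
            fh.write(f"{r.read_id}\t{r.status}\t{cfg}\t{r.score:.4f}\t{r.global_strand}\t{r.reason}\n")
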