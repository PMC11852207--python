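"""Reporter construct model.

A reporter shufflon is an ordered set of invertible "dummy" modules
separated (and flanked) by copies of a single 31-nt recombination site in
alternating orientation, with constant anchor sequences on both sides.
This module represents that construct and renders any module arrangement
("configuration") into a concrete DNA sequence.

Coordinates are 0-based half-open everywhere; positions in reports and
configuration strings are 1-based.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .sequtil import revcomp, random_dna, iter_kmers

__all__ = [
    "ModuleSpec",
    "SfxSite",
    "ShufflonDesign",
    "Configuration",
    "DesignError",
    "build_sequence",
    "render_reference_set",
    "default_design",
    "write_design",
    "read_design",
    "DEFAULT_MODULE_LENGTHS",
    "DEFAULT_ANCHOR_LENGTH",
    "ENUMERATION_CAP",
]

#: Module lengths used by the default five-module reporter (bp).  The
#: endpoints are fixed by the construct description; interior lengths are
#: evenly interpolated so every module length is unique and monotone.
DEFAULT_MODULE_LENGTHS: Tuple[int, ...] = (143, 237, 332, 426, 521)

#: Default anchor length per side (bp); two anchors plus the five-module
#: shufflon give an amplicon of ~4.3 kb.
DEFAULT_ANCHOR_LENGTH = 1250

#: Largest module count for which exhaustive enumeration is permitted.
ENUMERATION_CAP = 7

SITE_LEFT_ARM_LEN = 12
SITE_CORE_LEN = 7
SITE_RIGHT_ARM_LEN = 12
SITE_LEN = SITE_LEFT_ARM_LEN + SITE_CORE_LEN + SITE_RIGHT_ARM_LEN

_DNA_RE = re.compile(r"^[ACGT]+$")


class DesignError(ValueError):
    """Raised for invalid designs or configurations."""


@dataclass(frozen=True)
class ModuleSpec:
    """One invertible module of the reporter.

    Parameters
    ----------
    id
        1-based position of the module in the reference construct.
    sequence
        Forward-strand DNA of the module.
    """

    id: int
    sequence: str

    def __post_init__(self) -> None:
        if self.id < 1:
            raise DesignError(f"module id must be >= 1, got {self.id}")
        if not _DNA_RE.match(self.sequence):
            raise DesignError(f"module M{self.id}: sequence must be non-empty A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SfxSite:
    """A 31-nt recombination site: 12-bp left arm, 7-bp core, 12-bp right arm."""

    left_arm: str
    core: str
    right_arm: str

    def __post_init__(self) -> None:
        for name, part, want in (
            ("left_arm", self.left_arm, SITE_LEFT_ARM_LEN),
            ("core", self.core, SITE_CORE_LEN),
            ("right_arm", self.right_arm, SITE_RIGHT_ARM_LEN),
        ):
            if len(part) != want or not _DNA_RE.match(part):
                raise DesignError(f"site {name} must be {want} nt of A/C/G/T")

    @property
    def sequence(self) -> str:
        """The full 31-nt site on the forward strand."""
        return self.left_arm + self.core + self.right_arm

    @classmethod
    def from_sequence(cls, seq: str) -> "SfxSite":
        if len(seq) != SITE_LEN:
            raise DesignError(f"site sequence must be {SITE_LEN} nt, got {len(seq)}")
        return cls(seq[:12], seq[12:19], seq[19:])


@dataclass(frozen=True)
class Configuration:
    """A signed arrangement of modules.

    ``order[p]`` is the signed module id occupying 1-based position ``p+1``:
    positive for forward orientation, negative for inverted.  Valid
    configurations place each module only at positions of its own parity
    (a consequence of the alternating site orientations).
    """

    order: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.order or any(v == 0 for v in self.order):
            raise DesignError("configuration entries must be non-zero signed ids")

    @property
    def n(self) -> int:
        return len(self.order)

    @classmethod
    def reference(cls, n: int) -> "Configuration":
        """The unshuffled configuration ``(+1, +2, ..., +n)``."""
        return cls(tuple(range(1, n + 1)))

    @property
    def is_reference(self) -> bool:
        return self.order == tuple(range(1, self.n + 1))

    @property
    def unsigned_order(self) -> Tuple[int, ...]:
        return tuple(abs(v) for v in self.order)

    def is_valid(self) -> bool:
        """Check the id multiset and the position/id parity rule."""
        n = self.n
        if sorted(self.unsigned_order) != list(range(1, n + 1)):
            return False
        return all((p + 1 - abs(v)) % 2 == 0 for p, v in enumerate(self.order))

    def validate(self) -> "Configuration":
        if not self.is_valid():
            raise DesignError(f"invalid configuration {self.to_string()}: "
                              "id multiset must be 1..n and parities must match")
        return self

    def to_string(self) -> str:
        return "".join(("+" if v > 0 else "-") + str(abs(v)) for v in self.order)

    @classmethod
    def from_string(cls, s: str) -> "Configuration":
        parts = re.findall(r"[+-]\d+", s)
        if not parts or "".join(parts) != s:
            raise DesignError(f"cannot parse configuration string {s!r}")
        return cls(tuple(int(p) for p in parts))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


@dataclass(frozen=True)
class ShufflonDesign:
    """A full reporter: modules, the shared site, and two anchors.

    ``n + 1`` copies of the site are implied at the junctions, in
    alternating orientation (+, -, +, ...) starting with ``+`` at the
    left-most junction.  The site copies are identical for every
    configuration; only module content and orientation vary.
    """

    modules: Tuple[ModuleSpec, ...]
    site: SfxSite
    anchor_left: str
    anchor_right: str
    design_id: str = "shufflon"

    def __post_init__(self) -> None:
        if not self.modules:
            raise DesignError("design needs at least one module")
        ids = [m.id for m in self.modules]
        if ids != list(range(1, len(ids) + 1)):
            raise DesignError(f"module ids must be consecutive from 1, got {ids}")
        seqs = [m.sequence for m in self.modules]
        if len(set(seqs)) != len(seqs):
            raise DesignError("module sequences must be pairwise distinct")
        for a, name in ((self.anchor_left, "anchor_left"), (self.anchor_right, "anchor_right")):
            if not _DNA_RE.match(a):
                raise DesignError(f"{name} must be non-empty A/C/G/T")
        site = self.site.sequence
        site_rc = revcomp(site)
        for m in self.modules:
            if site in m.sequence or site_rc in m.sequence:
                raise DesignError(f"module M{m.id} contains the recombination site")

    @property
    def n(self) -> int:
        return len(self.modules)

    def module(self, module_id: int) -> ModuleSpec:
        return self.modules[module_id - 1]

    def site_at_junction(self, j: int) -> str:
        """Site sequence rendered at junction ``j`` (0-based, left to right)."""
        s = self.site.sequence
        return s if j % 2 == 0 else revcomp(s)

    @property
    def total_length(self) -> int:
        return (len(self.anchor_left) + len(self.anchor_right)
                + (self.n + 1) * SITE_LEN + sum(m.length for m in self.modules))

    def core_span(self) -> Tuple[int, int]:
        """0-based half-open span of the shuffled region (between anchors)."""
        return len(self.anchor_left), self.total_length - len(self.anchor_right)


def build_sequence(design: ShufflonDesign, config: Configuration) -> str:
    """Render a configuration of ``design`` to its amplicon DNA sequence.

    The layout is ``anchor_left + [site, module] * n + site + anchor_right``
    with site copies in fixed alternating orientation and each module
    reverse-complemented when its orientation is ``-``.
    """
    if config.n != design.n:
        raise DesignError(f"configuration has {config.n} modules, design has {design.n}")
    config.validate()
    parts: List[str] = [design.anchor_left]
    for p, signed in enumerate(config.order):
        parts.append(design.site_at_junction(p))
        seq = design.module(abs(signed)).sequence
        parts.append(seq if signed > 0 else revcomp(seq))
    parts.append(design.site_at_junction(design.n))
    parts.append(design.anchor_right)
    return "".join(parts)


def render_reference_set(design: ShufflonDesign, cap: int = ENUMERATION_CAP) -> Dict[str, str]:
    """One amplicon sequence per enumerable configuration.

    Returns a mapping from configuration string to DNA sequence, in the
    canonical (lexicographic) enumeration order.
    """
    from .combinatorics import enumerate_configurations

    if design.n > cap:
        raise DesignError(
            f"n={design.n} exceeds the enumeration cap ({cap}); "
            "use combinatorics.count_configurations for analytic counting")
    return {c.to_string(): build_sequence(design, c)
            for c in enumerate_configurations(design.n)}


# ---------------------------------------------------------------------------
# Default design generation
# ---------------------------------------------------------------------------

def _kmer_pool(seq: str, k: int) -> set:
    out = set()
    for _, km in iter_kmers(seq, k):
        out.add(km)
        out.add(revcomp(km))
    return out


def default_design(
    seed: int = 0,
    module_lengths: Sequence[int] = DEFAULT_MODULE_LENGTHS,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
    screen_k: int = 15,
    design_id: str = "shufflon",
) -> ShufflonDesign:
    """Deterministically generate a reporter design from a seed.

    Module and anchor sequences are drawn pseudo-randomly and screened so
    that no ``screen_k``-mer is shared between any two components (on
    either strand) — the uniqueness the marker decoder relies on — and so
    that no component contains the 31-nt site or its reverse complement.
    """
    rng = np.random.default_rng(seed)
    site = SfxSite.from_sequence(random_dna(rng, SITE_LEN))
    pool = _kmer_pool(site.sequence, screen_k)

    def draw(length: int) -> str:
        for _ in range(1000):
            cand = random_dna(rng, length)
            kmers = [cand[i:i + screen_k] for i in range(len(cand) - screen_k + 1)]
            if len(set(kmers)) != len(kmers):
                continue  # internal duplicate
            cand_pool = set(kmers) | {revcomp(km) for km in kmers}
            if pool & cand_pool:
                continue  # clash with a previously drawn component
            pool.update(cand_pool)
            return cand
        raise DesignError("could not draw a screened sequence; try another seed")

    modules = tuple(ModuleSpec(i + 1, draw(L)) for i, L in enumerate(module_lengths))
    anchor_left = draw(anchor_length)
    anchor_right = draw(anchor_length)
    return ShufflonDesign(modules, site, anchor_left, anchor_right, design_id=design_id)


# ---------------------------------------------------------------------------
# I/O: modules and anchors as FASTA, site and parameters as JSON
# ---------------------------------------------------------------------------

def write_design(design: ShufflonDesign, fasta_path, config_path) -> None:
    """Write a design as ``M1..Mn / anchor_L / anchor_R`` FASTA plus a JSON
    config holding the site arms and design id."""
    with open(fasta_path, "w") as fh:
        for m in design.modules:
            fh.write(f">M{m.id}\n{m.sequence}\n")
        fh.write(f">anchor_L\n{design.anchor_left}\n")
        fh.write(f">anchor_R\n{design.anchor_right}\n")
    cfg = {
        "design_id": design.design_id,
        "site": {
            "left_arm": design.site.left_arm,
            "core": design.site.core,
            "right_arm": design.site.right_arm,
        },
        "n_modules": design.n,
    }
    with open(config_path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_design(fasta_path, config_path) -> ShufflonDesign:
    """Inverse of :func:`write_design`."""
    from Bio import SeqIO

    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    with open(config_path) as fh:
        cfg = json.load(fh)
    n = int(cfg["n_modules"])
    try:
        modules = tuple(ModuleSpec(i, records[f"M{i}"]) for i in range(1, n + 1))
        anchor_left = records["anchor_L"]
        anchor_right = records["anchor_R"]
    except KeyError as exc:
        raise DesignError(f"design FASTA is missing record {exc}") from exc
    site = SfxSite(cfg["site"]["left_arm"], cfg["site"]["core"], cfg["site"]["right_arm"])
    return ShufflonDesign(modules, site, anchor_left, anchor_right,
                          design_id=cfg.get("design_id", "shufflon"))
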