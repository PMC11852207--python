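"""Summary statistics of a classified shufflon library.

Everything consumes a :class:`LibrarySummary` (configuration string ->
classified read count).  Replicate handling is explicit: callers either
pool counts with :func:`pool` or average per-replicate rates themselves;
nothing pools implicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import Configuration, DesignError, ShufflonDesign
from .combinatorics import reachable_set

__all__ = [
    "LibrarySummary",
    "DiversityResult",
    "pool",
    "shuffling_rate",
    "occupancy",
    "diversity",
    "expected_unique",
    "inversion_count_distribution",
    "inversion_frequency",
    "regress_inversion",
    "RegressionResult",
]


@dataclass
class LibrarySummary:
    """Read counts per configuration for one classified library."""

    design_id: str
    counts: Dict[str, int]
    n_unclassified: int = 0

    def __post_init__(self) -> None:
        for key, c in self.counts.items():
            Configuration.from_string(key).validate()
            if c < 0:
                raise DesignError(f"negative count for {key}")

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def n(self) -> int:
        if not self.counts:
            raise DesignError("empty summary has no module count")
        return Configuration.from_string(next(iter(self.counts))).n

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"design_id": self.design_id, "counts": self.counts,
                       "n_unclassified": self.n_unclassified}, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "LibrarySummary":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(obj["design_id"], {k: int(v) for k, v in obj["counts"].items()},
                   int(obj.get("n_unclassified", 0)))

    @classmethod
    def from_configurations(cls, configs: Iterable[Configuration],
                            design_id: str = "shufflon") -> "LibrarySummary":
        counts: Dict[str, int] = {}
        for c in configs:
            key = c.to_string()
            counts[key] = counts.get(key, 0) + 1
        return cls(design_id, counts)


def pool(summaries: Sequence[LibrarySummary], design_id: Optional[str] = None) -> LibrarySummary:
    """Sum counts across replicates (explicit pooling)."""
    if not summaries:
        raise DesignError("nothing to pool")
    counts: Dict[str, int] = {}
    n_uncl = 0
    for s in summaries:
        for k, v in s.counts.items():
            counts[k] = counts.get(k, 0) + v
        n_uncl += s.n_unclassified
    return LibrarySummary(design_id or summaries[0].design_id, counts, n_uncl)


def shuffling_rate(summary: LibrarySummary) -> float:
    """Fraction of classified reads not in the reference configuration."""
    total = summary.n_classified
    if total == 0:
        raise DesignError("cannot compute a shuffling rate on an empty summary")
    ref = Configuration.reference(summary.n).to_string()
    return 1.0 - summary.counts.get(ref, 0) / total


def occupancy(summary: LibrarySummary) -> pd.DataFrame:
    """Per-position distribution over signed modules.

    Rows are 1-based positions; columns are signed module labels
    ("+1", "-1", ...).  Each row sums to 1 over classified reads, and
    parity-forbidden cells are identically 0.
    """
    total = summary.n_classified
    if total == 0:
        raise DesignError("cannot compute occupancy on an empty summary")
    n = summary.n
    labels = [f"{sign}{m}" for m in range(1, n + 1) for sign in "+-"]
    mat = pd.DataFrame(0.0, index=pd.RangeIndex(1, n + 1, name="position"), columns=labels)
    for key, count in summary.counts.items():
        cfg = Configuration.from_string(key)
        for p, signed in enumerate(cfg.order, start=1):
            label = ("+" if signed > 0 else "-") + str(abs(signed))
            mat.at[p, label] += count / total
    return mat


@dataclass
class DiversityResult:
    sample_size: int
    unique_counts: np.ndarray          # unique configurations per draw
    rarefaction: pd.DataFrame          # columns: sample_size, mean_unique

    @property
    def mean_unique(self) -> float:
        return float(np.mean(self.unique_counts))


def expected_unique(probabilities: np.ndarray, sample_size: int) -> float:
    """Closed-form expected unique states when sampling with replacement."""
    p = np.asarray(probabilities, dtype=float)
    return float(np.sum(1.0 - (1.0 - p) ** sample_size))


def diversity(
    summary: LibrarySummary,
    sample_size: int = 4000,
    n_draws: int = 20,
    seed: int = 0,
    rarefaction_points: int = 12,
) -> DiversityResult:
    """Unique-configuration counts under subsampling with replacement.

    Members are drawn with replacement proportional to read counts;
    the rarefaction curve reports the mean unique count over ``n_draws``
    at a geometric grid of subsample sizes up to ``sample_size``.
    """
    if sample_size < 1:
        raise DesignError("sample_size must be >= 1")
    keys = sorted(summary.counts)
    weights = np.array([summary.counts[k] for k in keys], dtype=float)
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    grid = np.unique(np.geomspace(1, sample_size, rarefaction_points).astype(int))
    uniques = np.empty(n_draws, dtype=int)
    curve = np.zeros((n_draws, len(grid)))
    for d in range(n_draws):
        draws = rng.choice(len(keys), size=sample_size, p=probs)
        uniques[d] = len(np.unique(draws))
        for gi, g in enumerate(grid):
            curve[d, gi] = len(np.unique(draws[:g]))
    rare = pd.DataFrame({"sample_size": grid, "mean_unique": curve.mean(axis=0)})
    return DiversityResult(sample_size, uniques, rare)


def inversion_count_distribution(summary: LibrarySummary) -> pd.Series:
    """Fraction of classified reads at each minimal-event (BFS) depth.

    The mass at depth 0 equals ``1 - shuffling_rate`` exactly.
    """
    if summary.n_classified == 0:
        raise DesignError("empty summary")
    depths = {c.to_string(): d for c, d in reachable_set(summary.n).items()}
    hist: Dict[int, float] = {}
    total = summary.n_classified
    for key, count in summary.counts.items():
        d = depths[key]
        hist[d] = hist.get(d, 0.0) + count / total
    out = pd.Series(hist, name="fraction").sort_index()
    out.index.name = "depth"
    return out


def inversion_frequency(
    summaries: Mapping[str, LibrarySummary],
    design: ShufflonDesign,
) -> pd.DataFrame:
    """Per-module inversion frequency among reference-ORDER reads.

    Only configurations whose unsigned order is (1, 2, ..., n) contribute;
    for each module the frequency of the inverted orientation among those
    reads is reported per library ("SI" label).  Libraries with no
    reference-order reads yield rows with NaN frequency (flagged, not
    dropped).
    """
    if not summaries:
        raise DesignError("no summaries given")
    n = design.n
    ref_order = tuple(range(1, n + 1))
    rows = []
    for si_label, summary in summaries.items():
        inverted = {m.id: 0 for m in design.modules}
        n_ref_order = 0
        for key, count in summary.counts.items():
            cfg = Configuration.from_string(key)
            if cfg.unsigned_order != ref_order:
                continue
            n_ref_order += count
            for signed in cfg.order:
                if signed < 0:
                    inverted[-signed] += count
        for m in design.modules:
            freq = inverted[m.id] / n_ref_order if n_ref_order else float("nan")
            rows.append({"si": si_label, "module_id": m.id, "module_length": m.length,
                         "n_reference_order_reads": n_ref_order,
                         "n_inverted": inverted[m.id], "frequency": freq})
    return pd.DataFrame(rows)


@dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    table: pd.DataFrame

    @property
    def length_coefficient(self) -> float:
        return float(self.params["module_length"])

    @property
    def length_pvalue(self) -> float:
        return float(self.pvalues["module_length"])


def regress_inversion(table: pd.DataFrame) -> RegressionResult:
    """OLS of inversion frequency on module length plus library (SI) label.

    Module length enters as a continuous regressor; the SI enters as a
    treatment-coded categorical against the alphabetically first level.
    With a single SI level the categorical term is dropped (it would be
    collinear with the intercept).
    """
    import statsmodels.formula.api as smf

    data = table.dropna(subset=["frequency"]).copy()
    if data["module_length"].nunique() < 2:
        raise DesignError("regression needs >= 2 distinct module lengths "
                          "(module_length is collinear with the intercept)")
    formula = "frequency ~ module_length"
    if data["si"].nunique() >= 2:
        formula += " + C(si)"
    fit = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise DesignError("rank-deficient design matrix in regression")
    tidy = pd.DataFrame({"coef": fit.params, "se": fit.bse,
                         "t": fit.tvalues, "p": fit.pvalues})
    return RegressionResult(fit.params, fit.bse, fit.pvalues,
                            float(fit.fvalue), float(fit.f_pvalue), tidy)
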