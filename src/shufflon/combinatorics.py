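"""Parity-constrained signed permutations and the inversion-event model.

Modules sit between junctions 0..n (left to right); the site at junction
``j`` points forward when ``j`` is even.  An inversion event recombines two
junction sites of opposite orientation, i.e. a pair ``(i, j)`` with odd
span ``j - i``: the modules strictly between them are reversed in order and
each orientation bit is flipped.  Because an odd-length block reversal
preserves position parity, the closure of the reference under these events
is exactly the set of parity-valid signed permutations, of which there are
``ceil(n/2)! * floor(n/2)! * 2**n``.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from itertools import permutations, product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .design import Configuration, DesignError, ENUMERATION_CAP

__all__ = [
    "InversionEvent",
    "count_configurations",
    "enumerate_configurations",
    "apply_inversion",
    "valid_events",
    "reachable_set",
    "transition_matrix",
    "configuration_distribution",
    "predicted_shuffling_rate",
]


@dataclass(frozen=True, order=True)
class InversionEvent:
    """Recombination between junction sites ``site_i`` and ``site_j``.

    Only odd spans are valid: under the alternating site layout they are
    the pairs of sites in opposite orientation.
    """

    site_i: int
    site_j: int

    def __post_init__(self) -> None:
        if self.site_i < 0 or self.site_j <= self.site_i:
            raise DesignError(f"need 0 <= site_i < site_j, got ({self.site_i}, {self.site_j})")
        if (self.site_j - self.site_i) % 2 == 0:
            raise DesignError(
                f"event ({self.site_i}, {self.site_j}) has even span: "
                "same-orientation sites cannot recombine by inversion")

    @property
    def span(self) -> int:
        return self.site_j - self.site_i


def count_configurations(n: int) -> int:
    """Closed-form number of parity-valid signed permutations of n modules."""
    if n < 1:
        raise DesignError(f"module count must be >= 1, got {n}")
    return math.factorial((n + 1) // 2) * math.factorial(n // 2) * 2 ** n


def enumerate_configurations(n: int, cap: int = ENUMERATION_CAP) -> List[Configuration]:
    """All valid configurations in lexicographic order of the signed tuple."""
    if n < 1:
        raise DesignError(f"module count must be >= 1, got {n}")
    if n > cap:
        raise DesignError(f"n={n} exceeds the enumeration cap ({cap})")
    odd_ids = list(range(1, n + 1, 2))
    even_ids = list(range(2, n + 1, 2))
    out = []
    for odd_perm in permutations(odd_ids):
        for even_perm in permutations(even_ids):
            order = [0] * n
            order[0::2] = odd_perm
            order[1::2] = even_perm
            for signs in product((1, -1), repeat=n):
                out.append(Configuration(tuple(s * v for s, v in zip(signs, order))))
    out.sort(key=lambda c: c.order)
    return out


def valid_events(n: int) -> List[InversionEvent]:
    """All odd-span junction pairs for an n-module shufflon."""
    return [InversionEvent(i, j)
            for i in range(n + 1) for j in range(i + 1, n + 1)
            if (j - i) % 2 == 1]


def apply_inversion(config: Configuration, event: InversionEvent) -> Configuration:
    """Invert the block of modules between the event's junctions.

    Module p (1-based) sits between junctions p-1 and p, so the affected
    block is ``order[event.site_i : event.site_j]``.  Applying the same
    event twice returns the input.
    """
    if event.site_j > config.n:
        raise DesignError(f"event {event} out of range for n={config.n}")
    order = list(config.order)
    block = order[event.site_i:event.site_j]
    order[event.site_i:event.site_j] = [-v for v in reversed(block)]
    return Configuration(tuple(order))


def reachable_set(n: int, cap: int = ENUMERATION_CAP) -> Dict[Configuration, int]:
    """BFS closure of the reference under all valid events.

    Returns a mapping from configuration to its BFS depth, i.e. the minimal
    number of inversion events needed to produce it from the reference.
    """
    if n > cap:
        raise DesignError(f"n={n} exceeds the enumeration cap ({cap})")
    events = valid_events(n)
    start = Configuration.reference(n)
    depth: Dict[Configuration, int] = {start: 0}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for ev in events:
            nxt = apply_inversion(cur, ev)
            if nxt not in depth:
                depth[nxt] = depth[cur] + 1
                queue.append(nxt)
    return depth


# ---------------------------------------------------------------------------
# Markov-chain view of the event random walk
# ---------------------------------------------------------------------------

def transition_matrix(
    n: int,
    event_weights: Optional[Dict[InversionEvent, float]] = None,
) -> Tuple[np.ndarray, List[Configuration]]:
    """One-step transition matrix of the inversion random walk.

    Each step picks one valid event with probability proportional to its
    weight (uniform by default) and applies it.  Returns ``(P, states)``
    with states in canonical enumeration order; the reference is
    ``states.index(Configuration.reference(n))``.
    """
    states = enumerate_configurations(n)
    index = {c: i for i, c in enumerate(states)}
    events = valid_events(n)
    if event_weights is None:
        weights = np.ones(len(events))
    else:
        weights = np.array([float(event_weights.get(ev, 0.0)) for ev in events])
        if np.any(weights < 0) or weights.sum() <= 0:
            raise DesignError("event weights must be non-negative and not all zero")
    weights = weights / weights.sum()
    P = np.zeros((len(states), len(states)))
    for si, c in enumerate(states):
        for ev, w in zip(events, weights):
            P[si, index[apply_inversion(c, ev)]] += w
    return P, states


def configuration_distribution(
    n: int,
    event_rate: float,
    event_weights: Optional[Dict[InversionEvent, float]] = None,
) -> Tuple[np.ndarray, List[Configuration]]:
    """State distribution after a Poisson(event_rate) number of events.

    Mixing the k-step distributions over a Poisson count gives the matrix
    exponential ``expm(rate * (P - I))`` applied to the reference row.
    """
    from scipy.linalg import expm

    P, states = transition_matrix(n, event_weights)
    ref = states.index(Configuration.reference(n))
    Q = expm(event_rate * (P - np.eye(len(states))))
    return Q[ref], states


def predicted_shuffling_rate(
    n: int,
    event_rate: float,
    event_weights: Optional[Dict[InversionEvent, float]] = None,
) -> float:
    """Probability that a library member is not in the reference state
    after a Poisson(event_rate) number of inversion events."""
    dist, states = configuration_distribution(n, event_rate, event_weights)
    ref = states.index(Configuration.reference(n))
    return float(1.0 - dist[ref])
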