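"""Bit-parallel edit distance (Myers 1999, block formulation of Hyyro).

Used by the exhaustive read decoder, which needs many Levenshtein
distances between ~2 kb sequences.  The pattern is packed into 64-bit
blocks once and reused across texts; kernels are numba-compiled.

Two entry points:

- :func:`edit_distance` / :func:`batch_edit_distance` — global (NW, unit
  cost) Levenshtein distance.
- :func:`locate` — semi-global search of a probe (length a multiple of 64)
  in a text: free start/end in the text, returns the best end position.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from numba import njit

from .sequtil import encode

_ONE = np.uint64(1)
_ZERO = np.uint64(0)
_HIGH = np.uint64(1) << np.uint64(63)


def build_peq(pattern_codes: np.ndarray) -> np.ndarray:
    """Per-character bit masks of the pattern, shape (5, n_words)."""
    m = len(pattern_codes)
    words = (m + 63) // 64
    peq = np.zeros((5, max(words, 1)), dtype=np.uint64)
    for i, c in enumerate(pattern_codes):
        if c < 4:
            peq[c, i >> 6] |= _ONE << np.uint64(i & 63)
    return peq


@njit(cache=True)
def _popcount(x):
    n = 0
    while x:
        x &= x - _ONE
        n += 1
    return n


@njit(cache=True)
def _levenshtein_kernel(peq, m, text):
    words = peq.shape[1]
    Pv = np.empty(words, np.uint64)
    Mv = np.zeros(words, np.uint64)
    for b in range(words):
        Pv[b] = ~_ZERO
    for pos in range(text.shape[0]):
        c = text[pos]
        hin = 1  # Levenshtein: first row of the DP is 0,1,2,...
        for b in range(words):
            eq = peq[c, b] if c < 4 else _ZERO
            pv = Pv[b]
            mv = Mv[b]
            xv = eq | mv
            if hin < 0:
                eq |= _ONE
            xh = (((eq & pv) + pv) ^ pv) | eq
            ph = mv | ~(xh | pv)
            mh = pv & xh
            hout = 0
            if ph & _HIGH:
                hout = 1
            elif mh & _HIGH:
                hout = -1
            ph = ph << _ONE
            mh = mh << _ONE
            if hin > 0:
                ph |= _ONE
            elif hin < 0:
                mh |= _ONE
            Pv[b] = mh | ~(xv | ph)
            Mv[b] = ph & xv
            hin = hout
    # D[m][n] = n + (vertical +1 steps) - (vertical -1 steps) in last column
    dist = text.shape[0]
    full = m >> 6
    rem = m & 63
    for b in range(full):
        dist += _popcount(Pv[b]) - _popcount(Mv[b])
    if rem:
        mask = (_ONE << np.uint64(rem)) - _ONE
        dist += _popcount(Pv[full] & mask) - _popcount(Mv[full] & mask)
    return dist


@njit(cache=True)
def _batch_levenshtein_kernel(peq, m, texts):
    out = np.empty(texts.shape[0], np.int64)
    for r in range(texts.shape[0]):
        out[r] = _levenshtein_kernel(peq, m, texts[r])
    return out


@njit(cache=True)
def _semiglobal_kernel(peq, m, text):
    # requires m % 64 == 0 so the score lives at the top bit of the last block
    words = peq.shape[1]
    Pv = np.empty(words, np.uint64)
    Mv = np.zeros(words, np.uint64)
    for b in range(words):
        Pv[b] = ~_ZERO
    score = m
    best = m
    best_end = 0
    for pos in range(text.shape[0]):
        c = text[pos]
        hin = 0  # free start in the text
        for b in range(words):
            eq = peq[c, b] if c < 4 else _ZERO
            pv = Pv[b]
            mv = Mv[b]
            xv = eq | mv
            if hin < 0:
                eq |= _ONE
            xh = (((eq & pv) + pv) ^ pv) | eq
            ph = mv | ~(xh | pv)
            mh = pv & xh
            hout = 0
            if ph & _HIGH:
                hout = 1
            elif mh & _HIGH:
                hout = -1
            ph = ph << _ONE
            mh = mh << _ONE
            if hin > 0:
                ph |= _ONE
            elif hin < 0:
                mh |= _ONE
            Pv[b] = mh | ~(xv | ph)
            Mv[b] = ph & xv
            hin = hout
        score += hin
        if score < best:
            best = score
            best_end = pos + 1
    return best, best_end


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between two DNA strings."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) > len(b):  # pattern is packed into words; keep it the shorter one
        a, b = b, a
    pa = encode(a)
    return int(_levenshtein_kernel(build_peq(pa), len(pa), encode(b)))


def batch_edit_distance(pattern: str, texts_codes: np.ndarray) -> np.ndarray:
    """Distances from one pattern to each row of an encoded text matrix."""
    pa = encode(pattern)
    if len(pa) == 0:
        return np.full(texts_codes.shape[0], texts_codes.shape[1], dtype=np.int64)
    return _batch_levenshtein_kernel(build_peq(pa), len(pa), np.ascontiguousarray(texts_codes))


def locate(probe: str, text: str) -> Tuple[int, int]:
    """Best approximate occurrence of ``probe`` in ``text``.

    Returns ``(score, end)`` where ``score`` is the minimal edit distance of
    the probe to any text substring ending at ``end`` (0-based, exclusive).
    ``len(probe)`` must be a positive multiple of 64.
    """
    m = len(probe)
    if m == 0 or m % 64 != 0:
        raise ValueError("probe length must be a positive multiple of 64")
    if not text:
        return m, 0
    pa = encode(probe)
    score, end = _semiglobal_kernel(build_peq(pa), m, encode(text))
    return int(score), int(end)
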