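"""Bounded Levenshtein distance and the brute-force ground-truth oracle.

The pair test only needs the exact distance when it is <= dmax, so the
computation is threshold-bounded: edlib's banded bit-vector global
alignment with k = dmax returns the exact distance within the band and a
sentinel above it.  A cheap length-difference check short-circuits pairs
that cannot be within threshold.  N is an ordinary fifth symbol: N vs N
costs 0, N vs anything else costs 1.
"""

from __future__ import annotations

from typing import NamedTuple

import edlib

from .io import UniqueReadSet


class EdgeCandidate(NamedTuple):
    id_a: int
    id_b: int
    distance: int


def bounded_edit_distance(s1: str, s2: str, dmax: int) -> int | None:
    """Exact Levenshtein distance if <= dmax, else None."""
    if not s1 or not s2:
        raise ValueError("sequences must be non-empty")
    if abs(len(s1) - len(s2)) > dmax:
        return None
    d = edlib.align(s1, s2, mode="NW", task="distance", k=dmax)["editDistance"]
    return None if d == -1 else d


def ground_truth_edges(reads: UniqueReadSet, dmin: int, dmax: int
                       ) -> set[EdgeCandidate]:
    """All unordered pairs with dmin <= edit distance <= dmax, by
    exhaustive O(|R|^2) comparison.  Intended for <= ~5,000 unique reads."""
    if dmin < 1 or dmax < dmin:
        raise ValueError(f"invalid interval [{dmin}, {dmax}]")
    seqs = reads.sequences()
    n = len(seqs)
    align = edlib.align
    out: set[EdgeCandidate] = set()
    for i in range(n):
        si = seqs[i]
        li = len(si)
        for j in range(i + 1, n):
            sj = seqs[j]
            if abs(li - len(sj)) > dmax:
                continue
            d = align(si, sj, mode="NW", task="distance", k=dmax)["editDistance"]
            if d != -1 and d >= dmin:
                out.add(EdgeCandidate(i, j, d))
    return out
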