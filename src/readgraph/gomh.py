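"""Order-Min-Hash sketching over gapped k-mers (gOMH).

Reads stuck in large minimizer buckets share a substring by construction,
so plain minimizers can no longer split them.  gOMH re-buckets them by a
locality-sensitive sketch over *gapped* k-mers — k bases sampled at
stride 2 from consecutive start positions (span 2k-1), giving
l - 2k + 2 of them per read.  One sketching pass ("permutation") hashes
each gapped k-mer together with a seed and its running occurrence count
(1 on first sight, incrementing), in a single left-to-right sweep, and
keeps the minimum hash as the read's bucket key.  The occurrence counter
makes repeated gapped k-mers hash distinctly, so no partial sorting of
hashes is needed.

One permutation is generated per target distance dt in [dmin, dmax]
(gapped k-mer length from :func:`readgraph.params.gomh_k`); when the
interval yields fewer than ``floor`` permutations, dt values are cycled
with fresh seeds until the floor is met.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

from .minimizers import BucketMap, derive_seed
from .params import gomh_k


@dataclass(frozen=True)
class GomhPermutation:
    """One sketching pass: a seed, a gapped k-mer length and the edit
    distance dt in [dmin, dmax] it targets."""

    seed: int
    kprime: int
    dt: int

    def __post_init__(self) -> None:
        if self.kprime < 2:
            raise ValueError(f"kprime must be >= 2, got {self.kprime}")
        if self.dt < 1:
            raise ValueError(f"dt must be >= 1, got {self.dt}")


def gapped_kmers(sequence: str, kprime: int) -> list[str]:
    """All gapped k-mers: element i holds the bases at positions
    i, i+2, ..., i+2(kprime-1); there are l - 2*kprime + 2 of them.
    Returns [] when the read is too short (l < 2*kprime - 1)."""
    l = len(sequence)
    span = 2 * kprime - 1
    if l < span:
        return []
    return [sequence[i:i + span:2] for i in range(l - span + 1)]


def combine_hash(seed: int, item: str, occurrence: int) -> int:
    """64-bit mix of (seed, gapped k-mer, occurrence count)."""
    h = hashlib.blake2b(
        item.encode() + b"#" + occurrence.to_bytes(8, "little"),
        digest_size=8,
        key=(seed & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little"))
    return int.from_bytes(h.digest(), "little")


def gomh_value(sequence: str, perm: GomhPermutation,
               kprime: int | None = None) -> int | None:
    """Minimum combined hash over the read's gapped k-mers, or None when
    the read yields no gapped k-mer (caller buckets it whole).

    A single pass maintains a per-string running occurrence counter so
    repeated gapped k-mers produce distinct hash inputs.
    """
    kp = perm.kprime if kprime is None else kprime
    items = gapped_kmers(sequence, kp)
    if not items:
        return None
    occ: dict[str, int] = {}
    best: int | None = None
    for item in items:
        c = occ.get(item, 0) + 1
        occ[item] = c
        val = combine_hash(perm.seed, item, c)
        if best is None or val < best:
            best = val
    return best


def make_permutations(l: int, dmin: int, dmax: int, p2: float,
                      floor: int = 3, master_seed: int = 0
                      ) -> list[GomhPermutation]:
    """One permutation per dt in [max(1, dmin), dmax], cycled with fresh
    seeds until at least ``floor`` permutations exist."""
    if floor < 1:
        raise ValueError(f"floor must be >= 1, got {floor}")
    dts = list(range(max(1, dmin), dmax + 1))
    if not dts:
        raise ValueError(f"empty distance interval [{dmin}, {dmax}]")
    count = max(len(dts), floor)
    perms = []
    for i in range(count):
        dt = dts[i % len(dts)]
        perms.append(GomhPermutation(
            seed=derive_seed(master_seed, "gomh-perm", i),
            kprime=gomh_k(l, dt, p2),
            dt=dt))
    return perms


GOMH_SHORT_KEY = ("gshort",)


def gomh_bucket(reads: Iterable[tuple[int, str]],
                perms: Sequence[GomhPermutation],
                large_threshold: int = 10_000,
                p2: float | None = None,
                all_candidate_fallback: bool = False) -> BucketMap:
    """Bucket (id, sequence) pairs by gOMH value: each read joins exactly
    one bucket per permutation, keyed ("g", permutation index, value).

    When ``p2`` is given, the gapped k-mer length is re-derived per read
    from its own length (k' is a function of l), clamped at 2.  With
    ``all_candidate_fallback`` (UMI mode), a read whose gapped k-mer count
    does not exceed the permutation count skips min-hash selection and
    joins one bucket per distinct gapped k-mer candidate instead.
    """
    bmap = BucketMap(large_threshold=large_threshold)
    for rid, seq in reads:
        if all_candidate_fallback:
            kp = (gomh_k(len(seq), perms[0].dt, p2)
                  if p2 is not None else perms[0].kprime)
            cands = gapped_kmers(seq, kp)
            if cands and len(perms) >= len(cands):
                for cand in set(cands):
                    bmap.add(("ga", kp, cand), rid)
                continue
        placed = False
        for idx, perm in enumerate(perms):
            kp = (gomh_k(len(seq), perm.dt, p2)
                  if p2 is not None else perm.kprime)
            val = gomh_value(seq, perm, kprime=kp)
            if val is None:
                continue
            bmap.add(("g", idx, val), rid)
            placed = True
        if not placed:  # too short for any gapped k-mer: bucket whole
            bmap.add(GOMH_SHORT_KEY, rid)
    return bmap
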